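"""Synthetic cohorts with the statistical structure of imprinting-defect studies.

The generator emulates a three-group osteosarcoma methylation study:

* normal bone with imprinted differentially methylated regions (DMRs) at the
  monoallelic ~50% methylation level,
* early-onset tumors (< 30 y) with a ~19 percentage-point loss of methylation
  at the three 14q32 DMRs against only ~5 points at LINE-1 (the genome-wide
  surrogate),
* late-onset tumors (> 30 y) with a ~6-point 14q32 loss, comparable to LINE-1.

H19 defects are coupled to the 14q32 defect severity (target Pearson r 0.78)
while MEST and PEG3 stay undisturbed; patient-parent buccal triads carry the
reported parent-of-origin correlations (0.5 father/DMR-1, 0.63 mother/DMR-2);
bisulfite clone matrices realize the two-allele (one dense, one unmethylated)
pattern; expression decays and the event hazard rises with the 14q-index.

All percentages are on the 0-100 scale and clamped to [0, 100].  A single
seed drives everything through deterministic per-component substreams, so a
fixed config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .bisulfite import CloneMatrix, ReferenceAmplicon

__all__ = [
    "GROUPS",
    "DMRS_14Q",
    "IMPRINTED_GENES",
    "REFERENCE_GENE",
    "SimulationConfig",
    "CloneSimulation",
    "simulate_cohort",
    "simulate_clones",
    "simulate_triads",
    "simulate_outcomes",
]

GROUPS = ("normal", "early_onset", "late_onset")
AGE_CLASS = {"normal": "normal", "early_onset": "early", "late_onset": "late"}

#: loci emitted by simulate_cohort: (locus, dmr) pairs
DMRS_14Q = ("DMR-1", "DMR-2", "DMR-3")
OTHER_DMRS = (("H19", "H19-DMR"), ("MEST", "MEST-DMR"), ("PEG3", "PEG3-DMR"))

IMPRINTED_GENES = ("DLK1", "RTL1", "DIO3", "MEG3", "MEG8", "DIO3AS")
REFERENCE_GENE = "GAPDH"

# baseline delta-Ct of each gene vs GAPDH in normal tissue (higher = lower
# expression); RTL1/DIO3/MEG3 are the highly expressed cluster members
_BASE_DCT = {"MEG3": 2.0, "RTL1": 3.0, "DIO3": 3.0, "DLK1": 6.0, "MEG8": 6.0, "DIO3AS": 7.0}

_LN2 = math.log(2.0)


def _substream(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-component child stream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: group sizes 8/23/9, a 50%
    imprinted DMR baseline, 14q32 shifts of -19 (early onset) and -6 (late
    onset) percentage points, a -5 point LINE-1 shift, H19 coupling r = 0.78
    and triad correlations 0.5 / 0.63.  Within-group spreads are implementer
    calibrations (no variances are reported for the cohorts); the 8.8-point
    baseline SD makes the expected 14q-index of normals ~7.0 via
    E|N(0, s)| = s*sqrt(2/pi).
    """

    n_per_group: Mapping[str, int] | int = field(
        default_factory=lambda: {"normal": 8, "early_onset": 23, "late_onset": 9}
    )
    dmr_baseline_mean: float = 50.0
    dmr_baseline_sd: float = 8.8
    shift_14q_early: float = -19.0
    shift_14q_late: float = -6.0
    shift_line1: float = -5.0
    line1_baseline: float = 70.0
    line1_sd: float = 2.5
    other_locus_sd: float = 5.0
    h19_coupling_r: float = 0.78
    h19_extent_mean: float = 12.0
    h19_extent_sd: float = 5.0
    # patient-parent buccal triads
    triad_r_father_dmr1: float = 0.5
    triad_r_mother_dmr2: float = 0.63
    triad_mean_dmr1: float = 60.0
    triad_mean_dmr2: float = 70.0
    triad_sd: float = 5.0
    # bisulfite clone simulation
    n_clones: int = 10
    n_cpg: int = 20
    p_meth_dense: float = 0.9
    p_meth_sparse: float = 0.1
    conversion_efficiency: float = 0.99
    # expression / survival outcome models
    gamma: float = 1.0
    expression_noise_sd: float = 0.3
    h0: float = _LN2 / 60.0
    beta: float = 1.0
    censor_max: float = 120.0
    index_reference: float = 8.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in self.group_sizes().items():
            if n < 2:
                raise ValueError(f"n_per_group[{name!r}] must be >= 2, got {n}")
        for name in ("dmr_baseline_sd", "line1_sd", "other_locus_sd", "h19_extent_sd",
                     "triad_sd", "expression_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("h19_coupling_r", "triad_r_father_dmr1", "triad_r_mother_dmr2"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        for name in ("p_meth_dense", "p_meth_sparse", "conversion_efficiency"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.n_clones < 2:
            raise ValueError("n_clones must be >= 2")
        if self.n_cpg < 1:
            raise ValueError("n_cpg must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.h0 <= 0:
            raise ValueError("baseline hazard h0 must be > 0")
        if self.censor_max <= 0:
            raise ValueError("censor_max must be > 0")

    def group_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_group, int):
            return {g: self.n_per_group for g in GROUPS}
        return {g: int(self.n_per_group[g]) for g in GROUPS}

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        if not isinstance(payload["n_per_group"], int):
            payload["n_per_group"] = dict(payload["n_per_group"])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "SimulationConfig":
        return cls(**payload)


def _clip_pct(values: np.ndarray) -> np.ndarray:
    return np.clip(values, 0.0, 100.0)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the long-format methylation table of the three-group cohort.

    Returns rows (sample_id, group, age_class, locus, dmr, methylation_pct)
    for the three 14q32 DMRs, the H19/MEST/PEG3 DMRs and LINE-1 per sample.
    The H19 deviation extent is generated from the sample's realized 14q32
    deviations (standardized 14q-index mixed with independent noise at weight
    ``h19_coupling_r``), so the population correlation between the 14q-index
    and the H19 defect extent equals the configured target; a random sign
    yields both gain and loss of methylation at H19.
    """
    rng = _substream(config.seed, 0)
    sizes = config.group_sizes()
    shifts = {"normal": 0.0, "early_onset": config.shift_14q_early,
              "late_onset": config.shift_14q_late}

    sample_ids: list[str] = []
    groups: list[str] = []
    dmr_values: list[np.ndarray] = []
    line1: list[np.ndarray] = []
    other: dict[str, list[np.ndarray]] = {"MEST": [], "PEG3": []}

    for group in GROUPS:
        n = sizes[group]
        prefix = AGE_CLASS[group]
        sample_ids.extend(f"{prefix}-{i + 1:04d}" for i in range(n))
        groups.extend([group] * n)
        dmrs = config.dmr_baseline_mean + shifts[group] + rng.normal(
            0.0, config.dmr_baseline_sd, size=(n, len(DMRS_14Q)))
        dmr_values.append(_clip_pct(dmrs))
        line1_shift = 0.0 if group == "normal" else config.shift_line1
        line1.append(_clip_pct(config.line1_baseline + line1_shift
                               + rng.normal(0.0, config.line1_sd, size=n)))
        for locus in ("MEST", "PEG3"):
            other[locus].append(_clip_pct(
                config.dmr_baseline_mean + rng.normal(0.0, config.other_locus_sd, size=n)))

    dmr_mat = np.vstack(dmr_values)
    line1_arr = np.concatenate(line1)
    n_total = dmr_mat.shape[0]

    # H19 coupling through the realized 14q-index
    index = np.abs(dmr_mat - config.dmr_baseline_mean).mean(axis=1)
    sd = index.std()
    z = (index - index.mean()) / sd if sd > 0 else np.zeros(n_total)
    r = config.h19_coupling_r
    mix = r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(n_total)
    extent = np.clip(config.h19_extent_mean + config.h19_extent_sd * mix, 0.0, None)
    sign = rng.choice([-1.0, 1.0], size=n_total)
    h19 = _clip_pct(config.dmr_baseline_mean + sign * extent)

    records: list[dict] = []
    for i, (sid, group) in enumerate(zip(sample_ids, groups)):
        age_class = AGE_CLASS[group]
        for j, dmr in enumerate(DMRS_14Q):
            records.append({"sample_id": sid, "group": group, "age_class": age_class,
                            "locus": "14q32", "dmr": dmr,
                            "methylation_pct": dmr_mat[i, j]})
        records.append({"sample_id": sid, "group": group, "age_class": age_class,
                        "locus": "H19", "dmr": "H19-DMR", "methylation_pct": h19[i]})
        for locus in ("MEST", "PEG3"):
            records.append({"sample_id": sid, "group": group, "age_class": age_class,
                            "locus": locus, "dmr": f"{locus}-DMR",
                            "methylation_pct": np.concatenate(other[locus])[i]})
        records.append({"sample_id": sid, "group": group, "age_class": age_class,
                        "locus": "LINE1", "dmr": "LINE1",
                        "methylation_pct": line1_arr[i]})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# bisulfite clones

# building blocks for the synthetic amplicon; units start/end with T so no
# CpG can form across a junction
_CPG_UNIT = "TTACGTT"      # CpG cytosine at offset 3
_QC_UNIT = "TTCATT"        # non-CpG cytosine at offset 2


@dataclass(frozen=True)
class CloneSimulation:
    """Clones from a two-allele simulation plus their ground truth."""

    reference: ReferenceAmplicon
    clone_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    matrix: CloneMatrix          # apparent calls (after conversion failures)
    true_calls: np.ndarray       # methylation before conversion artifacts
    alleles: np.ndarray          # True = dense allele

    def to_fasta(self, reference_path: str, clones_path: str) -> None:
        ref = SeqRecord(Seq(self.reference.sequence), id="amplicon",
                        description="synthetic reference amplicon")
        SeqIO.write([ref], reference_path, "fasta")
        recs = [SeqRecord(Seq(seq), id=cid, description="bisulfite-converted clone")
                for cid, seq in zip(self.clone_ids, self.sequences)]
        SeqIO.write(recs, clones_path, "fasta")


def _build_reference(n_cpg: int, n_qc_c: int) -> ReferenceAmplicon:
    parts: list[str] = []
    cpg_pos: list[int] = []
    qc_pos: list[int] = []
    pos = 0
    remaining_cpg, remaining_qc = n_cpg, n_qc_c
    while remaining_cpg or remaining_qc:
        if remaining_cpg:
            cpg_pos.append(pos + 3)
            parts.append(_CPG_UNIT)
            pos += len(_CPG_UNIT)
            remaining_cpg -= 1
        if remaining_qc:
            qc_pos.append(pos + 2)
            parts.append(_QC_UNIT)
            pos += len(_QC_UNIT)
            remaining_qc -= 1
    return ReferenceAmplicon("".join(parts), tuple(cpg_pos), tuple(qc_pos))


def simulate_clones(
    p_dense: float,
    p_sparse: float,
    n_clones: int,
    n_cpg: int,
    conversion_efficiency: float = 1.0,
    seed: int = 0,
    n_non_cpg_c: int = 8,
) -> CloneSimulation:
    """Simulate bisulfite clones from a two-allele imprinted template.

    Each clone is assigned the dense or sparse allele with probability 1/2;
    per-CpG methylation is Bernoulli with the allele's rate.  Incomplete
    bisulfite conversion leaves an unmethylated cytosine (CpG or QC) reading
    as C with probability ``1 - conversion_efficiency``, so it appears
    methylated; the same artifact at non-CpG cytosines is what the
    conversion-QC statistic detects.  Sequences are emitted on the converted
    top strand only.
    """
    for name, p in (("p_dense", p_dense), ("p_sparse", p_sparse),
                    ("conversion_efficiency", conversion_efficiency)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if n_clones < 2:
        raise ValueError("n_clones must be >= 2")
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    if n_non_cpg_c < 5:
        raise ValueError("need >= 5 non-CpG cytosines for conversion QC")

    rng = _substream(seed, 1)
    reference = _build_reference(n_cpg, n_non_cpg_c)

    alleles = rng.random(n_clones) < 0.5
    p_allele = np.where(alleles, p_dense, p_sparse)
    true_calls = rng.random((n_clones, n_cpg)) < p_allele[:, None]
    cpg_retained = rng.random((n_clones, n_cpg)) >= conversion_efficiency
    apparent = true_calls | (~true_calls & cpg_retained)
    qc_retained = rng.random((n_clones, n_non_cpg_c)) >= conversion_efficiency

    template = list(reference.sequence)
    sequences: list[str] = []
    for i in range(n_clones):
        seq = template.copy()
        for j, p in enumerate(reference.cpg_positions):
            seq[p] = "C" if apparent[i, j] else "T"
        for k, p in enumerate(reference.non_cpg_c_positions):
            seq[p] = "C" if qc_retained[i, k] else "T"
        sequences.append("".join(seq))

    clone_ids = tuple(f"clone-{i + 1:05d}" for i in range(n_clones))
    conversion = 1.0 - qc_retained.mean(axis=1)
    matrix = CloneMatrix(apparent.astype(np.int8), clone_ids, conversion)
    return CloneSimulation(reference, clone_ids, tuple(sequences), matrix,
                           true_calls.astype(np.int8), alleles)


# ---------------------------------------------------------------------------
# triads

def simulate_triads(n_triads: int, config: SimulationConfig) -> pd.DataFrame:
    """Generate buccal DMR methylation for patient-mother-father triads.

    Child values are a correlation-weighted parental value plus independent
    noise, so the population Pearson r between child and father at DMR-1 is
    ``triad_r_father_dmr1`` and between child and mother at DMR-2 is
    ``triad_r_mother_dmr2`` (the other parent is uncorrelated at each DMR).
    Returns a long table (triad_id, member, dmr, methylation_pct).
    """
    if n_triads < 3:
        raise ValueError("n_triads must be >= 3")
    for r in (config.triad_r_father_dmr1, config.triad_r_mother_dmr2):
        if abs(r) > 1:
            raise ValueError("target correlations must lie in [-1, 1]")

    rng = _substream(config.seed, 2)
    sd = config.triad_sd
    specs = (
        ("DMR-1", config.triad_mean_dmr1, "father", config.triad_r_father_dmr1),
        ("DMR-2", config.triad_mean_dmr2, "mother", config.triad_r_mother_dmr2),
    )
    records: list[dict] = []
    for dmr, mu, coupled_parent, r in specs:
        father = mu + rng.normal(0.0, sd, n_triads)
        mother = mu + rng.normal(0.0, sd, n_triads)
        driver = father if coupled_parent == "father" else mother
        child = mu + r * (driver - mu) + sd * math.sqrt(1.0 - r * r) * rng.standard_normal(n_triads)
        values = {"father": _clip_pct(father), "mother": _clip_pct(mother),
                  "child": _clip_pct(child)}
        for i in range(n_triads):
            for member in ("child", "mother", "father"):
                records.append({"triad_id": f"triad-{i + 1:04d}", "member": member,
                                "dmr": dmr, "methylation_pct": values[member][i]})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# expression & survival outcomes

def simulate_outcomes(
    index_values: Sequence[float] | pd.Series,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate qPCR Ct and survival tables from per-sample 14q-index values.

    Imprinted-gene expression decays as ``exp(-gamma * index / 10)`` relative
    to the housekeeping gene (encoded as a delta-Ct increase of
    ``gamma/ln2 * index/10`` cycles plus noise), so higher indices give lower
    fold changes.  Event times are exponential with hazard
    ``h0 * exp(beta * (index - index_reference) / 10)`` under independent
    uniform censoring on (0, censor_max].

    Returns ``(ct_table, survival_table)`` with columns
    (sample_id, gene, ct) and (sample_id, time, event).
    """
    if isinstance(index_values, pd.Series):
        ids = [str(s) for s in index_values.index]
        idx = index_values.to_numpy(dtype=float)
    else:
        idx = np.asarray(index_values, dtype=float)
        ids = [f"S-{i + 1:04d}" for i in range(idx.size)]
    if idx.size == 0:
        raise ValueError("index_values is empty")
    if not np.all(np.isfinite(idx)):
        raise ValueError("index_values must be finite")
    if config.h0 <= 0:
        raise ValueError("baseline hazard h0 must be > 0")

    rng = _substream(config.seed, 3)
    n = idx.size

    ct_records: list[dict] = []
    ref_ct = 20.0 + rng.normal(0.0, 0.15, n)
    for i, sid in enumerate(ids):
        ct_records.append({"sample_id": sid, "gene": REFERENCE_GENE, "ct": ref_ct[i]})
    for gene in IMPRINTED_GENES:
        noise = rng.normal(0.0, config.expression_noise_sd, n)
        dct = _BASE_DCT[gene] + (config.gamma / _LN2) * idx / 10.0 + noise
        for i, sid in enumerate(ids):
            ct_records.append({"sample_id": sid, "gene": gene, "ct": ref_ct[i] + dct[i]})
    ct_table = pd.DataFrame.from_records(ct_records)

    hazard = config.h0 * np.exp(config.beta * (idx - config.index_reference) / 10.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censor_max, n)
    time = np.maximum(np.minimum(event_time, censor_time), 1e-9)
    event = (event_time <= censor_time).astype(int)
    survival = pd.DataFrame({"sample_id": ids, "time": time, "event": event})
    return ct_table, survival
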
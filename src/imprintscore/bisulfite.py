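"""Methylation calling from bisulfite-converted clone sequences.

After sodium-bisulfite treatment, unmethylated cytosines are deaminated and
read as T, while 5-methyl-cytosines remain C.  In a TA-cloning experiment each
sequenced clone is a single molecule (one parental allele), so a clones x CpG
matrix exposes allele-specific methylation directly: an imprinted region shows
one densely methylated and one unmethylated allele, averaging ~50%.

Cytosines outside CpG context are essentially never methylated in somatic
human tissue, so the fraction of non-CpG cytosines that were actually
converted to T measures the bisulfite conversion efficiency of each clone and
is used here as a per-clone QC statistic.

Coordinates are 0-based internally; user-facing reports add 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "METHYLATED",
    "UNMETHYLATED",
    "MISSING",
    "ReferenceAmplicon",
    "CloneMatrix",
    "MethylationSummary",
    "call_methylation",
    "build_clone_matrix",
    "clone_matrix_from_fasta",
    "summarize_matrix",
    "detect_imprinting_pattern",
    "DEFAULT_MIN_CONVERSION",
]

# integer codes for the calls matrix
METHYLATED = 1
UNMETHYLATED = 0
MISSING = -1

#: clones with conversion below this fraction are flagged and, by default,
#: excluded from summaries (field convention; the protocol states none).
DEFAULT_MIN_CONVERSION = 0.95

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceAmplicon:
    """Unconverted genomic reference for one bisulfite PCR amplicon.

    Parameters
    ----------
    sequence:
        Uppercase genomic sequence of the amplicon (top strand).
    cpg_positions:
        0-based offsets of the C of each CpG dinucleotide.
    non_cpg_c_positions:
        0-based offsets of cytosines not followed by G, used for
        conversion QC.
    """

    sequence: str
    cpg_positions: tuple[int, ...]
    non_cpg_c_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq:
            raise ValueError("reference sequence is empty")
        if set(seq) - _VALID_BASES:
            raise ValueError(f"reference contains non-ACGTN characters: {set(seq) - _VALID_BASES}")
        for p in self.cpg_positions:
            if not (0 <= p < len(seq) - 1 and seq[p] == "C" and seq[p + 1] == "G"):
                raise ValueError(f"position {p} is not the C of a CpG in the reference")
        for p in self.non_cpg_c_positions:
            if not (0 <= p < len(seq)) or seq[p] != "C":
                raise ValueError(f"position {p} is not a C in the reference")
            if p + 1 < len(seq) and seq[p + 1] == "G":
                raise ValueError(f"position {p} is in CpG context, not a QC cytosine")
        if set(self.cpg_positions) & set(self.non_cpg_c_positions):
            raise ValueError("CpG and non-CpG C position sets overlap")

    @classmethod
    def from_sequence(cls, sequence: str) -> "ReferenceAmplicon":
        """Scan a genomic sequence for CpG and non-CpG cytosine positions."""
        sequence = sequence.upper()
        cpg = []
        non_cpg = []
        for i, base in enumerate(sequence):
            if base != "C":
                continue
            if i + 1 < len(sequence) and sequence[i + 1] == "G":
                cpg.append(i)
            else:
                non_cpg.append(i)
        return cls(sequence, tuple(cpg), tuple(non_cpg))

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)


@dataclass
class CloneMatrix:
    """Clones x CpG methylation calls with per-clone conversion QC.

    ``calls`` uses the codes METHYLATED (1), UNMETHYLATED (0), MISSING (-1).
    ``conversion_rates`` holds the fraction of non-CpG cytosines read as T
    per clone (NaN when no QC cytosine was readable).
    """

    calls: np.ndarray
    clone_ids: tuple[str, ...]
    conversion_rates: np.ndarray
    min_conversion: float = DEFAULT_MIN_CONVERSION

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.conversion_rates = np.asarray(self.conversion_rates, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D clones x CpG array")
        n = self.calls.shape[0]
        if len(self.clone_ids) != n or self.conversion_rates.shape != (n,):
            raise ValueError("clone_ids / conversion_rates length mismatch with calls")

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]

    @property
    def n_cpg(self) -> int:
        return self.calls.shape[1]

    def flagged(self) -> np.ndarray:
        """Boolean mask of clones failing the conversion-QC threshold.

        A clone is flagged when its conversion rate is below
        ``min_conversion``; clones without readable QC cytosines (NaN rate)
        are not flagged.
        """
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.conversion_rates, nan=1.0) < self.min_conversion

    def subset(self, mask: np.ndarray) -> "CloneMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CloneMatrix(
            self.calls[mask],
            tuple(np.asarray(self.clone_ids, dtype=object)[mask]),
            self.conversion_rates[mask],
            self.min_conversion,
        )

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame (1-based CpG column labels)."""
        cols = [f"CpG_{j + 1}" for j in range(self.n_cpg)]
        df = pd.DataFrame(self.calls, index=list(self.clone_ids), columns=cols)
        df.index.name = "clone_id"
        return df


def call_methylation(
    reference: ReferenceAmplicon, clone_sequence: str
) -> tuple[np.ndarray, float]:
    """Call per-CpG methylation of one clone against its reference.

    At each CpG position a C is read as methylated, a T as unmethylated and
    any other base (including N) as missing.  The conversion rate is the
    fraction of non-CpG reference cytosines read as T among those read as
    C or T; NaN if none is readable.

    The clone must be a gapless, pre-trimmed sequence of the same length as
    the reference — alignment is upstream of this package.
    """
    if not clone_sequence:
        raise ValueError("clone sequence is empty")
    clone_sequence = clone_sequence.upper()
    if len(clone_sequence) != len(reference.sequence):
        raise ValueError(
            "clone length {} != reference length {}; clones must be pre-aligned "
            "and trimmed".format(len(clone_sequence), len(reference.sequence))
        )
    if set(clone_sequence) - _VALID_BASES:
        raise ValueError("clone contains non-ACGTN characters")

    calls = np.full(reference.n_cpg, MISSING, dtype=np.int8)
    for j, p in enumerate(reference.cpg_positions):
        base = clone_sequence[p]
        if base == "C":
            calls[j] = METHYLATED
        elif base == "T":
            calls[j] = UNMETHYLATED

    converted = retained = 0
    for p in reference.non_cpg_c_positions:
        base = clone_sequence[p]
        if base == "T":
            converted += 1
        elif base == "C":
            retained += 1
    total = converted + retained
    rate = converted / total if total else float("nan")
    return calls, rate


def build_clone_matrix(
    reference: ReferenceAmplicon,
    clones: Iterable[tuple[str, str]],
    min_conversion: float = DEFAULT_MIN_CONVERSION,
) -> CloneMatrix:
    """Call methylation for ``(clone_id, sequence)`` pairs into a CloneMatrix."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    rates: list[float] = []
    for clone_id, seq in clones:
        calls, rate = call_methylation(reference, seq)
        ids.append(clone_id)
        rows.append(calls)
        rates.append(rate)
    if not ids:
        raise ValueError("no clones provided")
    return CloneMatrix(np.vstack(rows), tuple(ids), np.array(rates), min_conversion)


def clone_matrix_from_fasta(
    reference_fasta: str,
    clones_fasta: str,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
) -> tuple[ReferenceAmplicon, CloneMatrix]:
    """Read a reference amplicon and clone FASTA files and call methylation."""
    ref_records = list(SeqIO.parse(reference_fasta, "fasta"))
    if len(ref_records) != 1:
        raise ValueError(f"expected exactly one reference sequence, found {len(ref_records)}")
    reference = ReferenceAmplicon.from_sequence(str(ref_records[0].seq))
    clones = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(clones_fasta, "fasta")]
    return reference, build_clone_matrix(reference, clones, min_conversion)


@dataclass(frozen=True)
class MethylationSummary:
    """Per-site, per-clone and overall percent methylation of a clone matrix."""

    per_site_pct: np.ndarray
    per_clone_pct: np.ndarray
    overall_pct: float
    n_clones_used: int
    n_clones_excluded_qc: int = 0
    clone_ids: tuple[str, ...] = field(default_factory=tuple)


def summarize_matrix(
    matrix: CloneMatrix, exclude_flagged: bool = True
) -> MethylationSummary:
    """Summarize a clone matrix as percent methylation.

    The overall level is the mean of per-clone means over non-missing calls
    (the average over sequenced molecules), matching how clone experiments
    are reported.  Clones failing conversion QC are excluded by default;
    clones with no informative call are always excluded.
    """
    work = matrix
    n_excluded_qc = 0
    if exclude_flagged:
        flagged = matrix.flagged()
        n_excluded_qc = int(flagged.sum())
        if n_excluded_qc:
            work = matrix.subset(~flagged)
    calls = np.ma.masked_equal(work.calls, MISSING)
    if calls.count() == 0:
        raise ValueError("clone matrix has no informative (non-missing) calls")

    per_site = 100.0 * calls.mean(axis=0)
    per_clone = 100.0 * calls.mean(axis=1)
    informative = ~np.ma.getmaskarray(per_clone)
    overall = float(per_clone[informative].mean())
    return MethylationSummary(
        per_site_pct=per_site.filled(np.nan),
        per_clone_pct=per_clone.filled(np.nan),
        overall_pct=overall,
        n_clones_used=int(informative.sum()),
        n_clones_excluded_qc=n_excluded_qc,
        clone_ids=work.clone_ids,
    )


def detect_imprinting_pattern(
    matrix: CloneMatrix,
    dense_cutoff: float = 0.7,
    sparse_cutoff: float = 0.3,
    balance_min: float = 0.2,
    imprinted_band: tuple[float, float] = (40.0, 60.0),
    hyper_min: float = 80.0,
    hypo_max: float = 20.0,
    exclude_flagged: bool = True,
) -> str:
    """Classify the allele pattern of a clone matrix.

    ``imprinted``: both a densely methylated (per-clone fraction >=
    ``dense_cutoff``) and an unmethylated (<= ``sparse_cutoff``) clone class
    are present at frequency >= ``balance_min`` and the overall level sits in
    the ~50% band — the monoallelic-methylation signature.
    ``hypermethylated`` / ``hypomethylated``: overall level beyond
    ``hyper_min`` / ``hypo_max`` (both alleles methylated or neither).
    ``mixed`` otherwise.
    """
    summary = summarize_matrix(matrix, exclude_flagged=exclude_flagged)
    per_clone = summary.per_clone_pct[~np.isnan(summary.per_clone_pct)]
    if per_clone.size < 4:
        raise ValueError(
            f"need >=4 informative clones to call a pattern, have {per_clone.size}"
        )
    frac = per_clone / 100.0
    dense = float(np.mean(frac >= dense_cutoff))
    sparse = float(np.mean(frac <= sparse_cutoff))
    overall = summary.overall_pct

    lo, hi = imprinted_band
    if dense >= balance_min and sparse >= balance_min and lo <= overall <= hi:
        return "imprinted"
    if overall >= hyper_min:
        return "hypermethylated"
    if overall <= hypo_max:
        return "hypomethylated"
    return "mixed"
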
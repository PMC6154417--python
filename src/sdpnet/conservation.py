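"""Column conservation, conservation classes, KL information, logo matrices.

Conservation of a column is the largest fraction of rows whose residue falls
in one physicochemical group. Gaps and 'X' belong to no group and therefore
count against conservation (the denominator includes every row): a gap at a
functionally required site is treated as a violation, not as missing data.

Classes follow the strict thresholds used in the curation workflow:
``strict`` means 100% group conservation, ``high`` means strictly above 95%
but below 100%, everything else is ``variable``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clades import CladeAssignment
from .errors import CladeError, UndefinedColumnError
from .msa import AA20, GAP, AlignmentMatrix, ReferenceMap

STRICT_CUT = 1.0
HIGH_CUT = 0.95

#: Physicochemical similarity groups (aromatic, aliphatic, basic, acidic,
#: amide, hydroxyl, small, plus singletons with distinctive chemistry).
#: Residues outside every named group form implicit singleton groups.
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "FYW": frozenset("FYW"),
    "ILVM": frozenset("ILVM"),
    "RKH": frozenset("RKH"),
    "DE": frozenset("DE"),
    "NQ": frozenset("NQ"),
    "ST": frozenset("ST"),
    "AG": frozenset("AG"),
    "C": frozenset("C"),
    "P": frozenset("P"),
}


def validate_groups(groups: dict[str, frozenset[str]]) -> None:
    seen: set[str] = set()
    for name, members in groups.items():
        if seen & set(members):
            raise ValueError(f"group {name!r} overlaps another group")
        if not set(members) <= set(AA20):
            raise ValueError(f"group {name!r} contains non-amino-acid letters")
        seen |= set(members)


def _full_groups(groups: dict[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    """Add singleton groups for residues not covered by any named group."""
    validate_groups(groups)
    covered = set().union(*groups.values()) if groups else set()
    full = dict(groups)
    for aa in AA20:
        if aa not in covered:
            full[aa] = frozenset(aa)
    return full


def column_conservation(
    msa: AlignmentMatrix,
    col: int,
    groups: dict[str, frozenset[str]] | None = None,
) -> tuple[str, float, float]:
    """(top group name, group conservation, gap fraction) for one column."""
    msa.check_col(col)
    full = _full_groups(DEFAULT_GROUPS if groups is None else groups)
    column = msa.column(col)
    n = len(column)
    best_name, best_count = "", 0
    for name, members in full.items():
        count = sum(1 for ch in column if ch in members)
        if count > best_count:
            best_name, best_count = name, count
    gap_fraction = column.count(GAP) / n
    return best_name, best_count / n, gap_fraction


def classify(conservation: float, strict_cut: float = STRICT_CUT,
             high_cut: float = HIGH_CUT) -> str:
    """strict iff 100%; high iff strictly between high_cut and 100%."""
    if conservation >= strict_cut:
        return "strict"
    if conservation > high_cut:
        return "high"
    return "variable"


def kl_information(
    msa: AlignmentMatrix,
    col: int,
    background: np.ndarray | None = None,
    rows: list[str] | None = None,
) -> float:
    """Kullback-Leibler information of a column in bits.

    sum_a p_a log2(p_a / q_a) over the residues observed among non-gap,
    non-'X' rows, against a strictly positive background q (default uniform
    1/20). Equals log2(20) - H(column) for a uniform background.
    """
    msa.check_col(col)
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or np.any(background <= 0):
        raise ValueError("background must be 20 strictly positive frequencies")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    column = msa.column(col)
    if rows is not None:
        keep = set(rows)
        column = "".join(ch for s, ch in zip(msa.sequences, column) if s.id in keep)
    counts = np.array([column.count(aa) for aa in AA20], dtype=float)
    total = counts.sum()
    if total == 0:
        raise UndefinedColumnError(
            f"column {col}: no non-gap residues; KL information undefined"
        )
    p = counts / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / background[nz])))


@dataclass
class ConservationProfile:
    """Per-column conservation table; ``frame`` carries the full profile."""

    frame: pd.DataFrame
    groups: dict[str, frozenset[str]] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def profile(
    msa: AlignmentMatrix,
    groups: dict[str, frozenset[str]] | None = None,
    background: np.ndarray | None = None,
    refmap: ReferenceMap | None = None,
    strict_cut: float = STRICT_CUT,
    high_cut: float = HIGH_CUT,
) -> ConservationProfile:
    """Full per-column profile: conservation, class, gap fraction, KL bits.

    All-gap columns get NaN KL information and are flagged in the
    ``undefined`` column rather than raising, so whole-alignment profiling
    survives alignments with insert-only regions.
    """
    groups = DEFAULT_GROUPS if groups is None else groups
    rows = []
    for col in range(1, msa.n_cols + 1):
        top, cons, gapf = column_conservation(msa, col, groups)
        try:
            kl = kl_information(msa, col, background)
            undefined = False
        except UndefinedColumnError:
            kl, undefined = float("nan"), True
        rows.append({
            "column": col,
            "ref_position": refmap.ref_of(col) if refmap else None,
            "top_group": top,
            "conservation": cons,
            "gap_fraction": gapf,
            "kl_bits": kl,
            "klass": classify(cons, strict_cut, high_cut),
            "undefined": undefined,
        })
    return ConservationProfile(frame=pd.DataFrame(rows), groups=dict(groups))


@dataclass
class LogoMatrix:
    """Per-clade residue frequencies and information content at chosen columns.

    ``frames`` maps clade label -> DataFrame indexed by column with one
    frequency column per amino acid plus ``info_bits`` (NaN where the column
    is all-gap within the clade).
    """

    frames: dict[str, pd.DataFrame]

    def to_tsv(self, path) -> None:
        parts = []
        for clade, df in self.frames.items():
            part = df.reset_index().rename(columns={"index": "column"})
            part.insert(0, "clade", clade)
            parts.append(part)
        pd.concat(parts, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def logo_matrices(
    msa: AlignmentMatrix,
    clades: CladeAssignment,
    cols: list[int],
    background: np.ndarray | None = None,
) -> LogoMatrix:
    """Per-clade frequency vectors over non-gap residues at the given columns."""
    frames: dict[str, pd.DataFrame] = {}
    for label in clades.labels:
        member_ids = clades.members(label)
        if not member_ids:
            raise CladeError(f"clade {label!r} has no sequences")
        records = {}
        for col in cols:
            msa.check_col(col)
            keep = set(member_ids)
            residues = [
                s.residues[col - 1]
                for s in msa.sequences
                if s.id in keep and s.residues[col - 1] in set(AA20)
            ]
            counts = np.array([residues.count(aa) for aa in AA20], dtype=float)
            total = counts.sum()
            rec = {aa: (counts[i] / total if total else 0.0) for i, aa in enumerate(AA20)}
            try:
                rec["info_bits"] = kl_information(msa, col, background, rows=member_ids)
            except UndefinedColumnError:
                rec["info_bits"] = float("nan")
            records[col] = rec
        frames[label] = pd.DataFrame.from_dict(records, orient="index")
        frames[label].index.name = "column"
    return LogoMatrix(frames=frames)
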
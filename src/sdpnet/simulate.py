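"""Synthetic MSA generator with planted, fully inspectable ground truth.

The generator emulates the statistical structure of a curated glutamic-
peptidase alignment: a few hundred sequences in a handful of clades over
~200 columns, with near-invariant hallmark columns (including the Q/E
catalytic-dyad positions), clade-diagnostic SDP columns, clade-independent
compensatory covarying column pairs, background substitution noise, sparse
gaps, and a minority of contaminant sequences that violate hallmark rules
(broken dyad, broken glycine, a long insert without homologous
counterparts, or a gap at a required site).

Clade founders share one common root sequence; clades differ only at the
planted SDP columns, so clade signal and covariation signal are decoupled
from background phylogenetic structure and every downstream claim (CDP,
network edge, scrutiny verdict) has an unambiguous planted truth. Hallmark
(rule) positions are never hit by background noise or gaps in clean rows,
so a correctly implemented rule engine must flag exactly the contaminants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .clades import CladeAssignment, roman, write_clade_table
from .errors import SpecError
from .msa import AA20, GAP, AlignedSequence, AlignmentMatrix, write_fasta

#: canonical residue at every hallmark rule position (reference numbering);
#: clean synthetic rows carry these exactly.
CANONICAL_RULE_RESIDUES: dict[int, str] = {
    8: "G", 41: "G", 43: "D", 44: "G", 51: "L", 53: "Q", 55: "G",
    67: "W", 72: "P", 89: "V", 105: "L", 133: "V", 136: "E",
}

CONTAMINANT_KINDS = (
    "dyad_violation", "glycine_violation", "long_insert", "gap_at_required",
)

INSERT_LENGTH = 18  # residues planted for the long-insert contaminant


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic alignment."""

    n_clades: int = 6
    seqs_per_clade: int = 40
    n_cols: int = 180
    conserved_cols: tuple[tuple[int, str], ...] = (
        (8, "G"), (41, "G"), (44, "G"), (51, "L"), (53, "Q"), (55, "G"),
        (67, "W"), (72, "P"), (89, "V"), (105, "L"), (133, "V"), (136, "E"),
    )
    sdp_cols: tuple[int, ...] = (15, 22, 30, 61, 80, 97, 112, 150)
    covarying_pairs: tuple[tuple[int, int], ...] = (
        (18, 64), (26, 84), (46, 102), (118, 141),
    )
    background_noise: float = 0.10
    gap_rate: float = 0.02
    n_contaminants: int = 5
    contaminant_kinds: tuple[str, ...] = (
        "dyad_violation", "glycine_violation", "long_insert",
        "gap_at_required", "dyad_violation",
    )
    noise_on_rule_positions: bool = False  # stress option
    seed: int = 1

    def validate(self) -> None:
        if self.n_clades < 2 or self.seqs_per_clade < 2:
            raise SpecError("need >= 2 clades of >= 2 sequences")
        if self.n_clades > 20:
            raise SpecError("more clades than residues available for SDP columns")
        if not (0 <= self.background_noise <= 1 and 0 <= self.gap_rate <= 1):
            raise SpecError("probabilities must be in [0,1]")
        if len(self.contaminant_kinds) != self.n_contaminants:
            raise SpecError("one contaminant kind per contaminant required")
        for kind in self.contaminant_kinds:
            if kind not in CONTAMINANT_KINDS:
                raise SpecError(f"unknown contaminant kind {kind!r}")
        cons = [c for c, _ in self.conserved_cols]
        cov = [c for pair in self.covarying_pairs for c in pair]
        planted = cons + list(self.sdp_cols) + cov
        if len(set(planted)) != len(planted):
            raise SpecError("planted column sets must be pairwise disjoint")
        rule_only = set(CANONICAL_RULE_RESIDUES) - set(cons)
        if set(self.sdp_cols) & set(CANONICAL_RULE_RESIDUES) or \
                set(cov) & set(CANONICAL_RULE_RESIDUES):
            raise SpecError("SDP/covarying columns may not sit on rule positions")
        if max(planted + list(CANONICAL_RULE_RESIDUES)) > self.n_cols:
            raise SpecError("planted columns exceed n_cols")
        for pos, res in self.conserved_cols:
            if pos in CANONICAL_RULE_RESIDUES and CANONICAL_RULE_RESIDUES[pos] != res:
                raise SpecError(
                    f"conserved column {pos} contradicts the hallmark residue"
                )


def default_spec() -> SyntheticSpec:
    """The default study conditions: 6 clades x 40 sequences, 180 columns,
    12 conserved hallmark columns (with the Q/E dyad), 8 SDP columns,
    4 covarying pairs, 10% noise, 2% gaps, 5 contaminants, seed 1."""
    return SyntheticSpec()


@dataclass
class SyntheticTruth:
    """Planted ground truth; every claim is verifiable against the MSA."""

    clades: dict[str, str]                       # id -> clade label
    sdp_columns: dict[int, dict[str, str]]       # col -> {clade: residue}
    covarying_pairs: list[dict]                  # {cols: [i, j], states: [[r,s],[r,s]]}
    contaminants: dict[str, str]                 # id -> kind
    reference_id: str
    conserved_columns: list[list]                # [col, residue]
    inserts: dict[str, list]                     # id -> [start_col, length]
    n_cols: int
    newick: str
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @property
    def clade_assignment(self) -> CladeAssignment:
        return CladeAssignment(dict(self.clades))

    @property
    def clean_ids(self) -> list[str]:
        return [i for i in self.clades if i not in self.contaminants]


def _mutate(rng: np.random.Generator, residue: str) -> str:
    choices = [aa for aa in AA20 if aa != residue]
    return choices[rng.integers(len(choices))]


def generate(spec: SyntheticSpec) -> tuple[AlignmentMatrix, SyntheticTruth]:
    """Generate the alignment and its truth; byte-deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AA20))

    # root sequence, with canonical residues at conserved and rule positions
    root = aa[rng.integers(20, size=spec.n_cols)].tolist()
    for pos, res in spec.conserved_cols:
        root[pos - 1] = res
    for pos, res in CANONICAL_RULE_RESIDUES.items():
        root[pos - 1] = res

    labels = [roman(i + 1) for i in range(spec.n_clades)]
    sdp_residues: dict[int, dict[str, str]] = {}
    for col in spec.sdp_cols:
        picks = aa[rng.choice(20, size=spec.n_clades, replace=False)]
        sdp_residues[col] = {lab: str(r) for lab, r in zip(labels, picks)}
    cov_states: list[dict] = []
    for (ci, cj) in spec.covarying_pairs:
        r1, r2 = aa[rng.choice(20, size=2, replace=False)]
        s1, s2 = aa[rng.choice(20, size=2, replace=False)]
        cov_states.append({"cols": [ci, cj],
                           "states": [[str(r1), str(s1)], [str(r2), str(s2)]]})

    protected = set(CANONICAL_RULE_RESIDUES) | {c for c, _ in spec.conserved_cols}
    gap_ok = [
        c for c in range(1, spec.n_cols + 1)
        if c not in protected
        and c not in spec.sdp_cols
        and c not in {x for p in spec.covarying_pairs for x in p}
    ]

    def clean_row(label: str, allow_gaps: bool) -> list[str]:
        row = list(root)
        for col in spec.sdp_cols:
            row[col - 1] = sdp_residues[col][label]
        for pair in cov_states:
            state = pair["states"][int(rng.random() < 0.5)]
            row[pair["cols"][0] - 1] = state[0]
            row[pair["cols"][1] - 1] = state[1]
        for col in range(1, spec.n_cols + 1):
            if col in protected and not spec.noise_on_rule_positions:
                continue
            if rng.random() < spec.background_noise:
                row[col - 1] = _mutate(rng, row[col - 1])
        if allow_gaps:
            for col in gap_ok:
                if rng.random() < spec.gap_rate:
                    row[col - 1] = GAP
        return row

    clades: dict[str, str] = {}
    rows: dict[str, list[str]] = {}
    reference_id = f"{labels[0]}_001"
    for lab in labels:
        for j in range(1, spec.seqs_per_clade + 1):
            sid = f"{lab}_{j:03d}"
            clades[sid] = lab
            rows[sid] = clean_row(lab, allow_gaps=(sid != reference_id))

    # contaminants copy an existing clean row, then apply their violation
    n_insert_cols = INSERT_LENGTH if "long_insert" in spec.contaminant_kinds else 0
    contaminants: dict[str, str] = {}
    inserts: dict[str, list] = {}
    dyad_toggle = 0
    contaminant_rows: dict[str, list[str]] = {}
    for i, kind in enumerate(spec.contaminant_kinds, start=1):
        lab = labels[(i - 1) % spec.n_clades]
        members = [s for s in clades if clades[s] == lab and s != reference_id]
        source = members[int(rng.integers(len(members)))]
        sid = f"CONT{i:02d}"
        row = list(rows[source])
        if kind == "dyad_violation":
            pos = 53 if dyad_toggle % 2 == 0 else 136
            dyad_toggle += 1
            row[pos - 1] = "K"
        elif kind == "glycine_violation":
            row[41 - 1] = "E"
        elif kind == "gap_at_required":
            row[133 - 1] = GAP
        elif kind == "long_insert":
            row = row + aa[rng.integers(20, size=INSERT_LENGTH)].tolist()
            inserts[sid] = [spec.n_cols + 1, INSERT_LENGTH]
        contaminant_rows[sid] = row
        contaminants[sid] = kind
        clades[sid] = lab

    total_cols = spec.n_cols + n_insert_cols
    sequences = []
    for sid, row in rows.items():
        padded = row + [GAP] * (total_cols - len(row))
        sequences.append(AlignedSequence(id=sid, description="synthetic clean",
                                         residues="".join(padded)))
    for sid, row in contaminant_rows.items():
        padded = row + [GAP] * (total_cols - len(row))
        sequences.append(AlignedSequence(
            id=sid, description=f"synthetic contaminant {contaminants[sid]}",
            residues="".join(padded)))
    msa = AlignmentMatrix(sequences)

    # star-like tree: one polytomy of clade subtrees, uniform supports
    subtrees = []
    for lab in labels:
        leaves = ",".join(s for s in clades if clades[s] == lab)
        subtrees.append(f"({leaves})0.99")
    newick = "(" + ",".join(subtrees) + ");"

    conserved = sorted(
        {(pos, res) for pos, res in spec.conserved_cols}
        | set(CANONICAL_RULE_RESIDUES.items())
    )
    truth = SyntheticTruth(
        clades=clades,
        sdp_columns=sdp_residues,
        covarying_pairs=cov_states,
        contaminants=contaminants,
        reference_id=reference_id,
        conserved_columns=[[p, r] for p, r in conserved],
        inserts=inserts,
        n_cols=total_cols,
        newick=newick,
        seed=spec.seed,
    )
    return msa, truth


def verify_truth(msa: AlignmentMatrix, truth: SyntheticTruth) -> list[str]:
    """Cross-check every truth claim against the emitted alignment.

    Conserved columns are exact in clean rows; SDP columns are checked by
    within-clade majority (background noise may flip individual rows);
    contaminant violations, reference integrity and insert coordinates are
    exact. Returns a list of human-readable inconsistencies (empty = ok)."""
    problems: list[str] = []
    by_id = {s.id: s.residues for s in msa.sequences}
    for sid in truth.clades:
        if sid not in by_id:
            problems.append(f"{sid} in truth but not in MSA")
    clean = [i for i in truth.clean_ids if i in by_id]
    for col, res in truth.conserved_columns:
        bad = [i for i in clean if by_id[i][col - 1] != res]
        if bad:
            problems.append(f"conserved col {col}!={res} in clean rows {bad[:3]}")
    for col_s, per_clade in truth.sdp_columns.items():
        col = int(col_s)
        for lab, res in per_clade.items():
            members = [i for i in clean if truth.clades[i] == lab]
            hits = sum(1 for i in members if by_id[i][col - 1] == res)
            if hits <= len(members) / 2:
                problems.append(f"SDP col {col} clade {lab}: planted {res} "
                                f"not the majority residue")
    ref = by_id.get(truth.reference_id, "")
    for pos, res in CANONICAL_RULE_RESIDUES.items():
        if ref[pos - 1] != res:
            problems.append(f"reference lacks canonical {res}{pos}")
    for sid, kind in truth.contaminants.items():
        row = by_id[sid]
        if kind == "dyad_violation" and row[53 - 1] == "Q" and row[136 - 1] == "E":
            problems.append(f"{sid}: dyad intact despite dyad_violation")
        if kind == "glycine_violation" and row[41 - 1] == "G":
            problems.append(f"{sid}: G41 intact despite glycine_violation")
        if kind == "gap_at_required" and row[133 - 1] != GAP:
            problems.append(f"{sid}: no gap at 133")
        if kind == "long_insert":
            start, length = truth.inserts[sid]
            segment = row[start - 1:start - 1 + length]
            if GAP in segment:
                problems.append(f"{sid}: insert region has gaps")
            others = [i for i in by_id if i != sid]
            if any(by_id[i][start - 1:start - 1 + length].strip(GAP) for i in others):
                problems.append(f"{sid}: insert region occupied by other rows")
    return problems


def write_bundle(msa: AlignmentMatrix, truth: SyntheticTruth,
                 outdir: str | Path) -> dict[str, Path]:
    """Write msa.fasta, clades.tsv, tree.nwk and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "msa": outdir / "msa.fasta",
        "clades": outdir / "clades.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    write_fasta(msa, paths["msa"])
    write_clade_table(truth.clade_assignment, paths["clades"])
    paths["tree"].write_text(truth.newick + "\n")
    truth.to_json(paths["truth"])
    return paths
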
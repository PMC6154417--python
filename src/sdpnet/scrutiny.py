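"""Hallmark-based sequence scrutiny: a declarative rule engine.

Sensitive homology searches for glutamic peptidases recover sequences that
may be non-functional homologs or broken gene models. The rules encoded
here remove sequences violating family hallmarks — the catalytic dyad
Q53/E136, four required glycines (8, 41, 44, 55), conserved hydrophobic
sites (51, 89, 105, 133), the turn residue 43 (D, or the tolerated S/G),
the 70's-loop proline 72, the substrate-stacking tryptophan 67 (for which
F is tolerated only when compensated by L105W), and long inserts lacking
homologous counterparts. Positions are reference (mature-chain) numbering
and resolve through a ReferenceMap; a gap at a required position violates
the rule, since a residue demanded for function cannot be absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import RuleConfigError
from .msa import GAP, AlignmentMatrix, ReferenceMap

DEFAULT_OCCUPANCY_CUT = 0.05
DEFAULT_INSERT_THRESHOLD = 15

KINDS = ("required_set", "forbidden_unless_paired", "no_gap", "max_insert")
SEVERITIES = ("remove", "warn")


@dataclass(frozen=True)
class ScrutinyRule:
    """One declarative rule.

    kinds:
      required_set            residue at ``position`` must be in ``allowed``
      forbidden_unless_paired ``residue`` at ``position`` is a violation
                              unless ``partner_position`` holds
                              ``partner_residue``
      no_gap                  ``position`` must not be gapped
      max_insert              no insert longer than ``threshold`` residues
    """

    kind: str
    label: str
    severity: str = "remove"
    position: int | None = None
    allowed: frozenset[str] = frozenset()
    residue: str | None = None
    partner_position: int | None = None
    partner_residue: str | None = None
    threshold: int | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise RuleConfigError(f"unknown rule kind {self.kind!r}")
        if self.severity not in SEVERITIES:
            raise RuleConfigError(f"unknown severity {self.severity!r}")
        if self.kind == "required_set" and not self.allowed:
            raise RuleConfigError(f"rule {self.label!r}: empty allowed set")
        if self.kind in ("required_set", "forbidden_unless_paired", "no_gap"):
            if self.position is None or self.position < 1:
                raise RuleConfigError(f"rule {self.label!r}: 1-based position required")
        if self.kind == "max_insert" and (self.threshold is None or self.threshold < 1):
            raise RuleConfigError(f"rule {self.label!r}: positive threshold required")


@dataclass
class ScrutinyRuleset:
    """Ordered rules plus metadata; at most one required_set per position."""

    rules: list[ScrutinyRule]
    name: str = "custom"
    version: str = "1"

    def __post_init__(self):
        seen: set[int] = set()
        for r in self.rules:
            if r.kind == "required_set":
                if r.position in seen:
                    raise RuleConfigError(
                        f"more than one required_set rule at position {r.position}"
                    )
                seen.add(r.position)

    @property
    def positions(self) -> set[int]:
        return {r.position for r in self.rules if r.position is not None} | {
            r.partner_position for r in self.rules if r.partner_position is not None
        }


def default_ruleset() -> ScrutinyRuleset:
    """The hallmark ruleset for eqolisin curation (reference numbering)."""
    req = lambda pos, allowed, label: ScrutinyRule(
        kind="required_set", position=pos, allowed=frozenset(allowed),
        severity="remove", label=label,
    )
    rules = [
        req(53, "Q", "Q53-catalytic"),
        req(136, "E", "E136-catalytic"),
        req(8, "G", "G8"),
        req(41, "G", "G41"),
        req(44, "G", "G44"),
        req(55, "G", "G55"),
        req(43, "DSG", "D43-turn"),
        req(51, "LIV", "hydrophobic-51"),
        # 67: W required; F tolerated, but only as the co-evolved W67F/L105W
        # pair — an uncompensated F is flagged, not removed.
        req(67, "WF", "W67"),
        ScrutinyRule(
            kind="forbidden_unless_paired", position=67, residue="F",
            partner_position=105, partner_residue="W", severity="warn",
            label="W67F-needs-L105W",
        ),
        req(72, "P", "P72-loop"),
        req(89, "VILMF", "hydrophobic-89"),
        # 105: small hydrophobic or F; W tolerated only as the co-evolved
        # pair with F67; E (buried charge) and Y are removed.
        req(105, "VILMFW", "hydrophobic-105"),
        ScrutinyRule(
            kind="forbidden_unless_paired", position=105, residue="W",
            partner_position=67, partner_residue="F", severity="remove",
            label="L105W-needs-W67F",
        ),
        req(133, "VILM", "hydrophobic-133"),
        ScrutinyRule(kind="no_gap", position=133, severity="remove",
                     label="no-gap-133"),
        ScrutinyRule(kind="max_insert", threshold=DEFAULT_INSERT_THRESHOLD,
                     severity="remove", label="long-insert"),
    ]
    return ScrutinyRuleset(rules=rules, name="eqolisin-hallmarks", version="1")


def load_ruleset(path: str | Path) -> ScrutinyRuleset:
    data = yaml.safe_load(Path(path).read_text())
    rules = []
    for raw in data["rules"]:
        raw = dict(raw)
        if "allowed" in raw:
            raw["allowed"] = frozenset(raw["allowed"])
        rules.append(ScrutinyRule(**raw))
    return ScrutinyRuleset(rules=rules, name=data.get("name", "custom"),
                           version=str(data.get("version", "1")))


def save_ruleset(ruleset: ScrutinyRuleset, path: str | Path) -> None:
    data = {
        "name": ruleset.name,
        "version": ruleset.version,
        "rules": [],
    }
    for r in ruleset.rules:
        d = {k: v for k, v in asdict(r).items() if v not in (None, frozenset())}
        if "allowed" in d:
            d["allowed"] = "".join(sorted(d["allowed"]))
        data["rules"].append(d)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def find_inserts(
    msa: AlignmentMatrix, occupancy_cut: float = DEFAULT_OCCUPANCY_CUT
) -> dict[str, list[tuple[int, int]]]:
    """Per-sequence inserts lacking homologous counterparts.

    An insert of a sequence is a maximal run of its non-gap residues confined
    to columns whose non-gap occupancy among the *other* rows is below
    ``occupancy_cut``. Returns {sequence id: [(start column, length), ...]}.
    """
    if not (0 < occupancy_cut < 1):
        raise ValueError(f"occupancy_cut must be in (0,1), got {occupancy_cut}")
    arr = msa.array
    nongap = arr != GAP
    col_counts = nongap.sum(axis=0)  # (n_cols,)
    n = msa.n_rows
    out: dict[str, list[tuple[int, int]]] = {}
    for i, seq in enumerate(msa.sequences):
        others = (col_counts - nongap[i]) / (n - 1)
        lonely = nongap[i] & (others < occupancy_cut)
        runs: list[tuple[int, int]] = []
        start = None
        for col in range(msa.n_cols):
            if lonely[col]:
                if start is None:
                    start = col
            elif start is not None:
                runs.append((start + 1, col - start))
                start = None
        if start is not None:
            runs.append((start + 1, msa.n_cols - start))
        out[seq.id] = runs
    return out


@dataclass
class ScrutinyReport:
    """Per-sequence verdicts with the full list of triggered rules."""

    verdicts: dict[str, str]  # id -> retained | removed | warned
    triggered: dict[str, list[tuple[str, str]]]  # id -> [(rule label, evidence)]
    ruleset_name: str = ""
    occupancy_cut: float = DEFAULT_OCCUPANCY_CUT

    def ids_with(self, verdict: str) -> list[str]:
        return [i for i, v in self.verdicts.items() if v == verdict]

    @property
    def retained(self) -> list[str]:
        # warned sequences are kept in the retained pool
        return [i for i, v in self.verdicts.items() if v != "removed"]

    @property
    def removed(self) -> list[str]:
        return self.ids_with("removed")

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "id": sid,
                "verdict": v,
                "triggered": ";".join(f"{lab}[{ev}]" for lab, ev in self.triggered[sid]),
            }
            for sid, v in self.verdicts.items()
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "ruleset": self.ruleset_name,
            "occupancy_cut": self.occupancy_cut,
            "sequences": {
                sid: {"verdict": v,
                      "triggered": [list(t) for t in self.triggered[sid]]}
                for sid, v in self.verdicts.items()
            },
        }


def scrutinize(
    msa: AlignmentMatrix,
    refmap: ReferenceMap,
    rules: ScrutinyRuleset | None = None,
    occupancy_cut: float = DEFAULT_OCCUPANCY_CUT,
) -> ScrutinyReport:
    """Apply a ruleset to every sequence; all triggered rules are reported.

    A sequence is removed when any rule with severity ``remove`` triggers,
    warned when only ``warn`` rules trigger, retained otherwise. The
    reference sequence must survive the ruleset — a removed reference means
    the ruleset and the coordinate system contradict each other.
    """
    rules = default_ruleset() if rules is None else rules
    # resolve rule positions once; unmapped position is a configuration error
    col_of: dict[int, int] = {}
    for pos in rules.positions:
        try:
            col_of[pos] = refmap.col_of(pos)
        except Exception as exc:
            raise RuleConfigError(
                f"rule position {pos} is not mapped by reference {refmap.ref_id!r}"
            ) from exc
    has_insert_rule = any(r.kind == "max_insert" for r in rules.rules)
    inserts = find_inserts(msa, occupancy_cut) if has_insert_rule else {}

    verdicts: dict[str, str] = {}
    triggered: dict[str, list[tuple[str, str]]] = {}
    for seq in msa.sequences:
        hits: list[tuple[str, str, str]] = []  # (label, evidence, severity)
        for rule in rules.rules:
            if rule.kind == "required_set":
                ch = seq.residues[col_of[rule.position] - 1]
                if ch not in rule.allowed:
                    hits.append((rule.label, f"{rule.position}{ch}", rule.severity))
            elif rule.kind == "forbidden_unless_paired":
                ch = seq.residues[col_of[rule.position] - 1]
                if ch == rule.residue:
                    partner = seq.residues[col_of[rule.partner_position] - 1]
                    if partner != rule.partner_residue:
                        hits.append((
                            rule.label,
                            f"{rule.position}{ch}/{rule.partner_position}{partner}",
                            rule.severity,
                        ))
            elif rule.kind == "no_gap":
                ch = seq.residues[col_of[rule.position] - 1]
                if ch == GAP:
                    hits.append((rule.label, f"{rule.position}-", rule.severity))
            elif rule.kind == "max_insert":
                for start, length in inserts.get(seq.id, []):
                    if length > rule.threshold:
                        hits.append((rule.label, f"col{start}+{length}aa", rule.severity))
        if any(sev == "remove" for _, _, sev in hits):
            verdicts[seq.id] = "removed"
        elif hits:
            verdicts[seq.id] = "warned"
        else:
            verdicts[seq.id] = "retained"
        triggered[seq.id] = [(lab, ev) for lab, ev, _ in hits]

    if verdicts.get(refmap.ref_id) == "removed":
        raise RuleConfigError(
            f"reference sequence {refmap.ref_id!r} fails the ruleset: "
            f"{triggered[refmap.ref_id]}"
        )
    return ScrutinyReport(
        verdicts=verdicts,
        triggered=triggered,
        ruleset_name=rules.name,
        occupancy_cut=occupancy_cut,
    )
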
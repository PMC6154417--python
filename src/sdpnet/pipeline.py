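"""End-to-end orchestration: conserve -> scrutinize -> clades -> sdp.

All randomness flows from one config seed; each permutation stage derives
its own sub-seed from the stage name, so running stages individually and
running the one-shot pipeline give identical outputs. Every output is a
plain TSV/JSON/FASTA file and the run manifest records config, per-file
SHA-256 digests and headline counts, making reruns byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import clades as clades_mod
from . import conservation as cons_mod
from . import network as net_mod
from . import scrutiny as scr_mod
from .errors import PipelineError
from .msa import AlignmentMatrix, map_reference, read_fasta, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and seed for one pipeline run."""

    msa: str
    ref_id: str
    out_dir: str
    tree: str | None = None
    clade_table: str | None = None
    ruleset: str | None = None          # YAML; default hallmark rules if None
    high_cut: float = cons_mod.HIGH_CUT
    z_cut: float = net_mod.DEFAULT_Z_CUT
    alpha: float = net_mod.DEFAULT_ALPHA
    min_clade_size: int = clades_mod.DEFAULT_MIN_SIZE
    min_support: float = clades_mod.DEFAULT_MIN_SUPPORT
    occupancy_cut: float = scr_mod.DEFAULT_OCCUPANCY_CUT
    n_perm_cdp: int = net_mod.DEFAULT_CDP_PERMUTATIONS
    n_perm_z: int = net_mod.DEFAULT_Z_PERMUTATIONS
    pseudocount: float = 0.0
    max_link: int = net_mod.DEFAULT_MAX_LINK
    seed: int = 1
    run_scrutiny: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.msa).exists():
            raise PipelineError("config", f"MSA not found: {self.msa}")
        if self.tree is None and self.clade_table is None:
            raise PipelineError(
                "config", "SDP analysis needs a tree or a clade table"
            )
        for name in ("tree", "clade_table", "ruleset"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{name} not found: {p}")
        for name, lo, hi in (
            ("high_cut", 0, 1), ("alpha", 0, 1), ("min_support", 0, 1),
            ("occupancy_cut", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise PipelineError("config", f"{name}={v} outside ({lo},{hi})")


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed derived from the run seed and the stage name."""
    return (base_seed * 100_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    counts: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _write_dot(net: net_mod.MINetwork, statuses: dict[int, str], path: Path) -> None:
    lines = ["graph mi_network {"]
    for node in sorted(net.graph.nodes):
        lines.append(f'  n{node} [label="{node}" status="{statuses.get(node, "none")}"];')
    for u, v, d in sorted(net.graph.edges(data=True)):
        lines.append(f'  n{u} -- n{v} [z="{d["z"]:.3f}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run all stages; identical config+inputs+seed give identical bytes."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    counts = manifest.counts

    def fail(stage: str, exc: Exception):
        manifest.warnings.append(f"stage {stage} failed: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # --- load -------------------------------------------------------------
    try:
        msa = read_fasta(config.msa)
        refmap = map_reference(msa, config.ref_id)
    except Exception as exc:
        fail("load", exc)
    counts["sequences_input"] = msa.n_rows
    counts["columns"] = msa.n_cols

    # --- conserve ---------------------------------------------------------
    try:
        prof = cons_mod.profile(msa, refmap=refmap, high_cut=config.high_cut)
        prof.to_tsv(out / "conservation.tsv")
    except Exception as exc:
        fail("conserve", exc)
    counts["strict_columns"] = int((prof.frame.klass == "strict").sum())
    counts["high_columns"] = int((prof.frame.klass == "high").sum())

    # --- scrutinize -------------------------------------------------------
    if config.run_scrutiny:
        try:
            ruleset = (scr_mod.load_ruleset(config.ruleset)
                       if config.ruleset else scr_mod.default_ruleset())
            report = scr_mod.scrutinize(msa, refmap, ruleset, config.occupancy_cut)
            report.to_frame().to_csv(out / "scrutiny.tsv", sep="\t", index=False)
            (out / "scrutiny.json").write_text(
                json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
            retained = msa.subset(report.retained)
            write_fasta(retained, out / "retained.fasta")
            if report.removed:
                write_fasta(msa.subset(report.removed), out / "removed.fasta")
        except Exception as exc:
            fail("scrutinize", exc)
        counts["sequences_retained"] = len(report.retained)
        counts["sequences_removed"] = len(report.removed)
        counts["sequences_warned"] = len(report.ids_with("warned"))
    else:
        retained = msa
        manifest.warnings.append("scrutiny disabled (--no-scrutiny)")
        counts["sequences_retained"] = msa.n_rows
        counts["sequences_removed"] = 0

    # --- clades -----------------------------------------------------------
    try:
        if config.clade_table:
            assignment = clades_mod.read_clade_table(config.clade_table)
        else:
            ptree = clades_mod.read_newick(config.tree)
            assignment = clades_mod.extract_clades(
                ptree, config.min_clade_size, config.min_support)
        assignment = assignment.restrict(retained.ids)
        clades_mod.write_clade_table(assignment, out / "clades_used.tsv")
    except Exception as exc:
        fail("clades", exc)
    counts["clades"] = len(assignment.labels)
    counts["orphans"] = retained.n_rows - len(assignment.assignment)

    # --- sdp --------------------------------------------------------------
    try:
        cdps = net_mod.identify_cdps(
            retained, assignment, alpha=config.alpha,
            n_perm=config.n_perm_cdp, seed=stage_seed(config.seed, "cdp"))
        cdps.insert(1, "ref_position",
                    [refmap.ref_of(int(c)) for c in cdps["column"]])
        cdps.to_csv(out / "cdp_table.tsv", sep="\t", index=False,
                    float_format="%.6g")

        mim = net_mod.mi_zscores(
            retained, n_perm=config.n_perm_z,
            seed=stage_seed(config.seed, "mi_null"),
            pseudocount=config.pseudocount)
        edges = mim.pair_frame()
        edges.insert(2, "ref_i", [refmap.ref_of(int(c)) for c in edges["col_i"]])
        edges.insert(3, "ref_j", [refmap.ref_of(int(c)) for c in edges["col_j"]])
        edges.to_csv(out / "mi_edges.tsv", sep="\t", index=False,
                     float_format="%.6g")

        net = net_mod.build_network(mim, z_cut=config.z_cut)
        sdp_report = net_mod.classify_sdps(cdps, net, max_link=config.max_link)
        (out / "sdp_report.json").write_text(
            json.dumps(sdp_report.to_json_dict(), indent=1, sort_keys=True))

        statuses = dict(zip(sdp_report.frame.column, sdp_report.frame.status))
        _write_dot(net, statuses, out / "network.dot")
        cumulative = net.cumulative
        with open(out / "node_attributes.tsv", "w") as fh:
            fh.write("node\tref_position\tcumulative_z\tkl_bits\tstatus\n")
            kl = dict(zip(prof.frame.column, prof.frame.kl_bits))
            for node in sorted(net.graph.nodes):
                fh.write(f"{node}\t{refmap.ref_of(node)}\t"
                         f"{cumulative[node]:.6g}\t{kl.get(node, float('nan')):.6g}\t"
                         f"{statuses.get(node, 'none')}\n")

        sdp_cols = sdp_report.psdps
        if sdp_cols:
            logos = cons_mod.logo_matrices(retained, assignment, sdp_cols)
            logos.to_tsv(out / "sdp_logos.tsv")
    except Exception as exc:
        fail("sdp", exc)
    counts["cdps"] = len(sdp_report.cdps)
    counts["psdps"] = len(sdp_report.psdps)
    counts["sdps"] = len(sdp_report.sdps)
    counts["sdns"] = len(sdp_report.sdns)
    counts["network_nodes"] = net.graph.number_of_nodes()
    counts["network_edges"] = net.graph.number_of_edges()

    manifest.metadata["approximations"] = [
        "conservation denominator includes gap rows (a gap counts against "
        "conservation)",
        "SDP confirmation approximated by SDN connectivity "
        f"(max_link={config.max_link})",
        "MI significance is a permutation z-score against a column-shuffle null",
    ]
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.digests[f.name] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest
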
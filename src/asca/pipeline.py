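"""End-to-end orchestration: combine -> dedup -> align -> tree -> site analysis.

Each stage consumes and emits the standard formats (FASTA, aligned FASTA /
Clustal, Newick, TSV/JSON), so an externally computed alignment or tree can
replace the built-in stage and flow through identical downstream code.  A
run is fully determined by its configuration: rerunning with the same
config reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .coordmap import (
    ClusterConfig,
    FingerprintMatrix,
    build_position_map,
    default_cluster_config,
    fingerprint_matrix,
    load_cluster_config,
    validate_reference,
    write_fingerprint_tsv,
)
from .msa import Alignment, default_scoring, progressive_msa, read_alignment, write_alignment
from .phylo import (
    extract_clades,
    leaf_labels,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    root_with_outgroup,
    write_newick,
)
from .seqio import merge_and_deduplicate, read_fasta, write_fasta
from .sitecluster import (
    assign_subfamilies,
    clade_profiles,
    detect_loop,
    rank_candidates,
    write_candidates_tsv,
    write_clade_profiles_tsv,
    write_family_overview_tsv,
    write_loop_calls_tsv,
    write_subfamily_json,
)

logger = logging.getLogger("asca")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see the CLI for the same knobs."""

    fasta_paths: tuple[str, ...] = ()
    alignment_path: str | None = None  # skip the built-in aligner
    tree_path: str | None = None  # skip neighbor joining
    reference_id: str = ""
    cluster_config_path: str | None = None  # default: packaged VAO clusters
    loop_start: int | None = None
    loop_end: int | None = None
    loop_threshold: float = 0.5
    outgroup_ids: tuple[str, ...] = ()
    k_clades: int | None = None
    membership_path: str | None = None
    rank_within: tuple[str, ...] = ()  # default: every clade
    rank_scope: tuple[str, ...] = ()  # default: all clusters
    present_frac: float = 0.9
    absent_frac: float = 0.1
    seed: int = 0
    out_dir: str = "asca_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = dict(raw)
        for key in ("fasta_paths", "outgroup_ids", "rank_within", "rank_scope"):
            if key in coerced and coerced[key] is not None:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory results of a run, alongside the files written to out_dir."""

    config: RunConfig
    alignment: Alignment
    fingerprints: FingerprintMatrix
    tree: object  # rooted dendropy.Tree
    clades: dict[str, set[str]]
    loop_calls: list
    subfamilies: object  # SubfamilyAssignment
    ranking: list[tuple[str, int]]
    dropped: dict[str, list[str]]
    artifacts: dict[str, Path] = field(default_factory=dict)


def _read_membership(path: str | Path) -> dict[str, str]:
    mapping = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("seq_id"):
                continue
            sid, label = line.split("\t")[:2]
            mapping[sid] = label
    return mapping


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every stage and write the artifact files.

    Raises :class:`PipelineError` with a stage tag on the first failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- input / dedup ----------------------------------------------------
    name = stage("dedup")
    try:
        sets = [read_fasta(p) for p in cfg.fasta_paths]
        if not sets and cfg.alignment_path is None:
            raise ValueError("no input FASTA files")
        records, dropped = merge_and_deduplicate(sets) if sets else ([], {})
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise PipelineError(name, str(exc)) from exc

    # --- alignment --------------------------------------------------------
    name = stage("align")
    try:
        if cfg.alignment_path is not None:
            aln = read_alignment(cfg.alignment_path)
            if records:
                expected = {r.id: r.residues for r in records}
                for rid in aln.ids:
                    if rid in expected and aln.ungapped(rid) != expected[rid]:
                        raise ValueError(
                            f"imported alignment row {rid!r} disagrees with input sequence"
                        )
        else:
            if len(records) < 2:
                raise ValueError("need at least 2 sequences to align")
            aln = progressive_msa(records, default_scoring())
        artifacts["alignment"] = out / "alignment.afa"
        write_alignment(aln, artifacts["alignment"])
        if records:
            artifacts["unique_fasta"] = out / "unique.fasta"
            write_fasta(records, artifacts["unique_fasta"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- fingerprints -----------------------------------------------------
    name = stage("fingerprint")
    try:
        config = (
            load_cluster_config(cfg.cluster_config_path)
            if cfg.cluster_config_path
            else default_cluster_config()
        )
        ref_id = cfg.reference_id or config.reference_id
        if not ref_id:
            raise ValueError("no reference id given (config or --ref-id)")
        validate_reference(aln, ref_id, config)
        fm = fingerprint_matrix(aln, config.clusters, ref_id)
        pm = build_position_map(aln, ref_id)
        artifacts["fingerprints"] = out / "fingerprints.tsv"
        write_fingerprint_tsv(fm, artifacts["fingerprints"])
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- tree -------------------------------------------------------------
    name = stage("tree")
    try:
        if cfg.tree_path is not None:
            tree = read_newick(cfg.tree_path)
            if leaf_labels(tree) != set(aln.ids):
                raise ValueError("tree leaf labels do not match alignment ids")
        else:
            dm = p_distance_matrix(aln)
            artifacts["distances"] = out / "distances.tsv"
            dm.write_tsv(artifacts["distances"])
            tree = neighbor_joining(dm)
        if cfg.outgroup_ids:
            tree = root_with_outgroup(tree, cfg.outgroup_ids)
        artifacts["tree"] = out / "tree.nwk"
        write_newick(tree, artifacts["tree"])
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- clades -----------------------------------------------------------
    name = stage("clades")
    try:
        membership = (
            _read_membership(cfg.membership_path) if cfg.membership_path else None
        )
        clades = extract_clades(
            tree,
            k=cfg.k_clades,
            membership=membership,
            outgroup_ids=cfg.outgroup_ids,
        )
        artifacts["clades"] = out / "clades.tsv"
        with artifacts["clades"].open("w") as fh:
            fh.write("seq_id\tclade\n")
            for label in sorted(clades):
                for sid in sorted(clades[label]):
                    fh.write(f"{sid}\t{label}\n")
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- loop + subfamilies + profiles + ranking ---------------------------
    name = stage("report")
    try:
        if cfg.loop_start is None or cfg.loop_end is None:
            raise ValueError("loop span (start, end) is required configuration")
        calls = detect_loop(
            aln, (cfg.loop_start, cfg.loop_end), pm, threshold=cfg.loop_threshold
        )
        ingroup_calls = [
            c for c in calls if c.seq_id not in set(cfg.outgroup_ids)
        ]
        assignment = assign_subfamilies(
            clades,
            ingroup_calls,
            present_frac=cfg.present_frac,
            absent_frac=cfg.absent_frac,
        )
        profiles = clade_profiles(fm, clades)
        within = cfg.rank_within or tuple(sorted(clades))
        ranking = rank_candidates(
            fm,
            fm.get(ref_id),
            clades,
            within=within,
            scope=cfg.rank_scope or None,
        )
        artifacts["loop_calls"] = out / "loop_calls.tsv"
        write_loop_calls_tsv(calls, artifacts["loop_calls"])
        artifacts["subfamilies"] = out / "subfamilies.json"
        write_subfamily_json(assignment, clades, artifacts["subfamilies"])
        artifacts["clade_profiles"] = out / "clade_profiles.tsv"
        write_clade_profiles_tsv(profiles, artifacts["clade_profiles"])
        artifacts["candidates"] = out / "candidates.tsv"
        write_candidates_tsv(ranking, artifacts["candidates"])
        artifacts["overview"] = out / "family_overview.tsv"
        write_family_overview_tsv(tree, fm, clades, calls, artifacts["overview"])
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- run log ----------------------------------------------------------
    artifacts["run_log"] = out / "run_log.json"
    artifacts["run_log"].write_text(
        json.dumps(
            {
                "version": __version__,
                "seed": cfg.seed,
                "config_sha256": cfg.digest(),
                "config": cfg.to_dict(),
                "n_input": sum(len(s) for s in sets) if sets else 0,
                "n_unique": len(records),
                "artifacts": {k: str(v) for k, v in artifacts.items()},
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return PipelineResult(
        config=cfg,
        alignment=aln,
        fingerprints=fm,
        tree=tree,
        clades=clades,
        loop_calls=calls,
        subfamilies=assignment,
        ranking=ranking,
        dropped=dropped,
        artifacts=artifacts,
    )
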
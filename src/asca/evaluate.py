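"""Scoring pipeline output against simulation truth.

Given a simulated family (which carries machine-readable truth for every
stage) and a pipeline result, these helpers measure how much of the planted
structure the analysis recovered: fingerprint symbols, loop calls, the clade
partition, and the loop-based subfamily split.  They are used by the test
suite, the analysis drivers and the acceptance script alike.
"""

from __future__ import annotations

from pathlib import Path

from .pipeline import PipelineResult, RunConfig, run_pipeline
from .seqio import write_fasta
from .synthetic_data import SimulatedFamily, default_vao_scenario, simulate_family


def scenario_run_config(
    family: SimulatedFamily, fasta_path: str | Path, out_dir: str | Path
) -> RunConfig:
    """Pipeline configuration matching a simulated family.

    The reference is the first leaf of clade C4 (the clade that keeps the
    reference active-site states in the default scenario); the loop span and
    clade count come from the simulation spec; the outgroup is the simulated
    bacterial-style clade.
    """
    spec = family.spec
    ref_id = "C4_leaf01" if spec.n_clades >= 4 else family.ingroup_ids[0]
    return RunConfig(
        fasta_paths=(str(fasta_path),),
        reference_id=ref_id,
        loop_start=spec.loop_start,
        loop_end=spec.loop_end,
        outgroup_ids=tuple(family.outgroup_ids),
        k_clades=spec.n_clades,
        seed=spec.seed,
        out_dir=str(out_dir),
    )


def run_scenario(seed: int, out_dir: str | Path) -> tuple[SimulatedFamily, PipelineResult]:
    """Simulate the default scenario and run the full pipeline on it."""
    out_dir = Path(out_dir)
    family = simulate_family(default_vao_scenario(seed))
    sim_dir = out_dir / "simulated"
    paths = family.write(sim_dir)
    cfg = scenario_run_config(family, paths["fasta"], out_dir / "pipeline")
    return family, run_pipeline(cfg)


def fingerprint_recovery(result: PipelineResult, family: SimulatedFamily) -> float:
    """Fraction of (sequence, position) cells equal to the planted symbol.

    Only cells whose position was protected in the simulation are scored;
    sequences lacking the loop are scored at the same positions (the loop
    never overlaps protected positions by construction).
    """
    ok = total = 0
    for fp in result.fingerprints.fingerprints:
        truth = family.planted_fingerprints.get(fp.seq_id)
        if truth is None:
            continue
        for _, pos, symbol in fp.entries:
            if pos in truth:
                total += 1
                ok += symbol == truth[pos]
    if total == 0:
        raise ValueError("no scored cells: do cluster positions match the spec?")
    return ok / total


def loop_call_accuracy(result: PipelineResult, family: SimulatedFamily) -> float:
    """Fraction of sequences whose loop call matches the planted state."""
    calls = {c.seq_id: c.present for c in result.loop_calls}
    scored = [sid for sid in calls if sid in family.loop_state]
    if not scored:
        raise ValueError("no overlapping sequences between calls and truth")
    return sum(calls[sid] == family.loop_state[sid] for sid in scored) / len(scored)


def _partition(groups) -> set[frozenset[str]]:
    return {frozenset(members) for members in groups}


def clade_partition_matches(result: PipelineResult, family: SimulatedFamily) -> bool:
    """Does the recovered ingroup partition equal the planted clades?"""
    truth: dict[str, set[str]] = {}
    for sid in family.ingroup_ids:
        truth.setdefault(family.clade_of[sid], set()).add(sid)
    return _partition(result.clades.values()) == _partition(truth.values())


def subfamily_leaf_partition(result: PipelineResult) -> set[frozenset[str]]:
    """Recovered subfamilies as sets of leaf ids."""
    out = set()
    for members in result.subfamilies.subfamilies.values():
        leaves: set[str] = set()
        for clade in members:
            leaves |= result.clades[clade]
        out.add(frozenset(leaves))
    return out


def subfamily_recovered(result: PipelineResult, family: SimulatedFamily) -> bool:
    """Does the recovered subfamily split equal the planted loop split?"""
    with_loop = frozenset(
        sid for sid in family.ingroup_ids if family.loop_state[sid]
    )
    without = frozenset(
        sid for sid in family.ingroup_ids if not family.loop_state[sid]
    )
    truth = {s for s in (with_loop, without) if s}
    return subfamily_leaf_partition(result) == truth
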
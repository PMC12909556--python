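"""Clade-level active-site analysis and subfamily delineation.

Once the family is aligned, fingerprinted and grouped into clades, this
module answers the comparative questions: what is each clade's consensus
active-site motif and how conserved is it; which sequences carry the
oligomerization loop (an indel that, for the vanillyl alcohol oxidase
family, separates the octamer-forming subfamily from the dimeric one); how
do the clades fall into subfamilies; and which members diverge most from
the reference active site and are therefore interesting candidates.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .coordmap import (
    Fingerprint,
    FingerprintMatrix,
    PositionMap,
    fingerprint_distance,
)
from .msa import Alignment
from .seqio import GAP


@dataclass(frozen=True)
class CladeProfile:
    """Consensus fingerprint and per-position conservation for one clade."""

    label: str
    members: tuple[str, ...]
    consensus: Fingerprint
    conservation: tuple[float, ...]  # fraction showing the modal symbol


@dataclass(frozen=True)
class LoopCall:
    """Loop presence for one sequence: fraction of loop columns occupied."""

    seq_id: str
    occupancy: float
    present: bool


@dataclass(frozen=True)
class SubfamilyAssignment:
    """Partition of clades into subfamilies by shared loop state."""

    subfamilies: Mapping[str, tuple[str, ...]]  # label -> clade labels
    clade_states: Mapping[str, str]  # clade -> present / absent / mixed
    unassigned: tuple[str, ...]  # mixed clades


def _modal_symbol(symbols: Iterable[str]) -> tuple[str, int]:
    """Modal symbol with ties broken alphabetically, the gap sorting last."""
    counts = Counter(symbols)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0] != GAP, _neg(kv[0])))
    return best[0], best[1]


def _neg(sym: str):
    # max() picks the highest key; invert the symbol so that alphabetically
    # earlier symbols win ties
    return tuple(-ord(c) for c in sym)


def clade_profiles(
    fm: FingerprintMatrix, clades: Mapping[str, Iterable[str]]
) -> list[CladeProfile]:
    """Per-clade modal symbol and conservation at every scaffold position."""
    profiles = []
    for label in sorted(clades):
        members = tuple(sorted(clades[label]))
        if not members:
            raise ValueError(f"clade {label!r} is empty")
        fps = [fm.get(m) for m in members]
        scaffold = fps[0].scaffold()
        entries = []
        conservation = []
        for idx, (cname, pos) in enumerate(scaffold):
            symbols = [fp.entries[idx][2] for fp in fps]
            modal, count = _modal_symbol(symbols)
            entries.append((cname, pos, modal))
            conservation.append(count / len(members))
        profiles.append(
            CladeProfile(
                label=label,
                members=members,
                consensus=Fingerprint(seq_id=f"consensus:{label}", entries=tuple(entries)),
                conservation=tuple(conservation),
            )
        )
    return profiles


def detect_loop(
    aln: Alignment,
    loop_region: tuple[int, int],
    pm: PositionMap,
    threshold: float = 0.5,
) -> list[LoopCall]:
    """Call loop presence per sequence from occupancy of the loop columns.

    ``loop_region`` is (start, end) inclusive in 1-based reference
    numbering; occupancy is the non-gap fraction over the mapped columns.
    """
    start, end = loop_region
    if not (1 <= start <= end <= pm.ref_length):
        raise ValueError(
            f"loop region {start}..{end} outside reference (length {pm.ref_length})"
        )
    cols = [pm.column(p) for p in range(start, end + 1)]
    calls = []
    for rid, row in aln.rows:
        occupied = sum(1 for c in cols if row[c] != GAP)
        occ = occupied / len(cols)
        calls.append(LoopCall(seq_id=rid, occupancy=occ, present=occ >= threshold))
    return calls


def assign_subfamilies(
    clades: Mapping[str, Iterable[str]],
    loops: Sequence[LoopCall],
    present_frac: float = 0.9,
    absent_frac: float = 0.1,
) -> SubfamilyAssignment:
    """Group clades into subfamilies by consensus loop state.

    A clade is loop-positive when at least ``present_frac`` of its members
    carry the loop, loop-negative when at most ``absent_frac`` do, and
    otherwise mixed.  Subfamilies are the maximal groups of clades sharing a
    non-mixed state (so there are at most two); mixed clades are reported
    but left unassigned.
    """
    call_by_id = {c.seq_id: c for c in loops}
    states: dict[str, str] = {}
    for label in sorted(clades):
        members = list(clades[label])
        missing = [m for m in members if m not in call_by_id]
        if missing:
            raise ValueError(f"no loop call for members {missing} of clade {label!r}")
        frac = sum(call_by_id[m].present for m in members) / len(members)
        if frac >= present_frac:
            states[label] = "present"
        elif frac <= absent_frac:
            states[label] = "absent"
        else:
            states[label] = "mixed"
    groups: dict[str, list[str]] = {}
    for label, state in states.items():
        if state != "mixed":
            groups.setdefault(state, []).append(label)
    # deterministic labels: larger subfamily first, ties by state name
    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )
    subfamilies = {
        f"SF{i + 1}": tuple(sorted(members)) for i, (_, members) in enumerate(ordered)
    }
    unassigned = tuple(sorted(l for l, s in states.items() if s == "mixed"))
    return SubfamilyAssignment(
        subfamilies=subfamilies, clade_states=states, unassigned=unassigned
    )


def rank_candidates(
    fm: FingerprintMatrix,
    reference_fp: Fingerprint,
    clades: Mapping[str, Iterable[str]],
    within: Iterable[str],
    scope: Iterable[str] | None = None,
) -> list[tuple[str, int]]:
    """Rank members of the chosen clades by active-site divergence.

    Distance is the fingerprint Hamming distance to the reference over the
    chosen cluster scope; ties order by sequence id.  The most divergent
    candidates — the interesting ones for characterization — come first.
    """
    within = set(within)
    unknown = within - set(clades)
    if unknown:
        raise ValueError(f"unknown clade labels: {sorted(unknown)}")
    pool = sorted({m for label in within for m in clades[label]})
    if not pool:
        raise ValueError("no sequences in the selected clades")
    scored = [
        (sid, fingerprint_distance(fm.get(sid), reference_fp, scope=scope))
        for sid in pool
    ]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def write_clade_profiles_tsv(profiles: Sequence[CladeProfile], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("clade\tcluster\tposition\tconsensus\tconservation\tn_members\n")
        for prof in profiles:
            for (cname, pos, sym), cons in zip(
                prof.consensus.entries, prof.conservation
            ):
                fh.write(
                    f"{prof.label}\t{cname}\t{pos}\t{sym}\t{cons:.4f}\t{len(prof.members)}\n"
                )


def write_loop_calls_tsv(calls: Sequence[LoopCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("seq_id\toccupancy\tpresent\n")
        for c in calls:
            fh.write(f"{c.seq_id}\t{c.occupancy:.4f}\t{int(c.present)}\n")


def write_subfamily_json(
    assignment: SubfamilyAssignment,
    clades: Mapping[str, Iterable[str]],
    path: str | Path,
) -> None:
    payload = {
        "subfamilies": {
            label: {
                "clades": list(members),
                "n_sequences": sum(len(list(clades[c])) for c in members),
            }
            for label, members in assignment.subfamilies.items()
        },
        "clade_loop_states": dict(assignment.clade_states),
        "unassigned_clades": list(assignment.unassigned),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_candidates_tsv(
    ranking: Sequence[tuple[str, int]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("rank\tseq_id\tactive_site_distance\n")
        for rank, (sid, dist) in enumerate(ranking, start=1):
            fh.write(f"{rank}\t{sid}\t{dist}\n")


def write_family_overview_tsv(
    tree: dendropy.Tree,
    fm: FingerprintMatrix,
    clades: Mapping[str, Iterable[str]],
    loops: Sequence[LoopCall],
    path: str | Path,
) -> None:
    """Tree-ordered summary joining clade, per-cluster motifs, and loop state.

    One row per leaf in the rooted tree's traversal order — the tabular
    counterpart of the classic tree-plus-motif figure.
    """
    clade_of = {m: label for label, members in clades.items() for m in members}
    loop_of = {c.seq_id: c for c in loops}
    cluster_names = [c.name for c in fm.clusters]
    with Path(path).open("w") as fh:
        header = ["seq_id", "clade"] + [f"{n}_motif" for n in cluster_names]
        header += ["loop_occupancy", "loop_present"]
        fh.write("\t".join(header) + "\n")
        for leaf in tree.leaf_node_iter():
            sid = leaf.taxon.label
            fp = fm.get(sid)
            call = loop_of.get(sid)
            row = [sid, clade_of.get(sid, "outgroup")]
            row += [fp.motif(n) for n in cluster_names]
            row += [
                f"{call.occupancy:.4f}" if call else "NA",
                str(int(call.present)) if call else "NA",
            ]
            fh.write("\t".join(row) + "\n")
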
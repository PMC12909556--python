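"""Reference-anchored coordinate mapping and active-site fingerprints.

The comparative analysis of an enzyme family is organised around a reference
sequence whose active-site residues are known (for vanillyl alcohol oxidases:
PsVAO, with 21 first-shell residues grouped into the five functional clusters
A, H, P, T and W).  Positions are given in 1-based reference numbering (e.g.
"L316"); this module carries those positions through an alignment to every
homolog and extracts each sequence's active-site *fingerprint* — the ordered
string of residues it presents at the mapped positions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .msa import Alignment
from .seqio import GAP

#: symbols that never match anything in fingerprint comparisons, not even
#: themselves: a gap (deletion) and X (ambiguity) carry no residue identity.
OPAQUE_SYMBOLS = frozenset({GAP, "X"})


@dataclass(frozen=True)
class ClusterDefinition:
    """A named active-site cluster: ordered 1-based reference positions."""

    name: str
    positions: tuple[int, ...]
    role: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("cluster name must be non-empty")
        if not self.positions:
            raise ValueError(f"cluster {self.name!r}: no positions")
        if any(p < 1 for p in self.positions):
            raise ValueError(f"cluster {self.name!r}: positions are 1-based")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError(
                f"cluster {self.name!r}: positions must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.positions)


def validate_clusters(clusters: Sequence[ClusterDefinition]) -> None:
    """Check cross-cluster invariants: unique names, disjoint positions."""
    names = [c.name for c in clusters]
    if len(set(names)) != len(names):
        raise ValueError("cluster names must be unique")
    seen: dict[int, str] = {}
    for c in clusters:
        for p in c.positions:
            if p in seen:
                raise ValueError(
                    f"position {p} belongs to clusters {seen[p]!r} and {c.name!r}"
                )
            seen[p] = c.name


@dataclass(frozen=True)
class PositionMap:
    """Mapping from 1-based reference residue index to 0-based column."""

    ref_id: str
    pairs: Mapping[int, int]

    def column(self, position: int) -> int:
        try:
            return self.pairs[position]
        except KeyError:
            raise KeyError(
                f"position {position} outside reference {self.ref_id!r} "
                f"(length {len(self.pairs)})"
            ) from None

    @property
    def ref_length(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Fingerprint:
    """Residues one sequence presents at the mapped cluster positions.

    ``entries`` is ordered by cluster then position; symbols are amino acids,
    X, or "-" where the sequence is gapped at the mapped column.
    """

    seq_id: str
    entries: tuple[tuple[str, int, str], ...]  # (cluster, ref position, symbol)

    def scaffold(self) -> tuple[tuple[str, int], ...]:
        return tuple((c, p) for c, p, _ in self.entries)

    def symbols(self) -> tuple[str, ...]:
        return tuple(s for _, _, s in self.entries)

    def motif(self, cluster: str) -> str:
        return "".join(s for c, _, s in self.entries if c == cluster)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class FingerprintMatrix:
    """One fingerprint per alignment row, on a shared scaffold."""

    clusters: tuple[ClusterDefinition, ...]
    fingerprints: tuple[Fingerprint, ...]

    def __post_init__(self) -> None:
        scaffolds = {fp.scaffold() for fp in self.fingerprints}
        if len(scaffolds) > 1:
            raise ValueError("fingerprints disagree in scaffolding")

    def get(self, seq_id: str) -> Fingerprint:
        for fp in self.fingerprints:
            if fp.seq_id == seq_id:
                return fp
        raise KeyError(f"no fingerprint for {seq_id!r}")

    @property
    def ids(self) -> list[str]:
        return [fp.seq_id for fp in self.fingerprints]


def build_position_map(aln: Alignment, ref_id: str) -> PositionMap:
    """Map every reference residue to its alignment column.

    The k-th non-gap character of the reference row maps residue index k
    (1-based) to that column (0-based); the map is strictly monotone and
    covers exactly the ungapped reference length.
    """
    row = aln.row(ref_id)  # KeyError if absent
    pairs: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            k += 1
            pairs[k] = col
    if not pairs:
        raise ValueError(f"reference row {ref_id!r} is all gaps")
    return PositionMap(ref_id=ref_id, pairs=pairs)


def extract_fingerprint(
    aln: Alignment,
    pm: PositionMap,
    clusters: Sequence[ClusterDefinition],
    seq_id: str,
) -> Fingerprint:
    """Read the symbols one sequence shows at the mapped cluster positions."""
    bad = [p for c in clusters for p in c.positions if p > pm.ref_length]
    if bad:
        raise ValueError(
            f"cluster positions {bad} exceed reference length {pm.ref_length}"
        )
    row = aln.row(seq_id)
    entries = tuple(
        (c.name, p, row[pm.column(p)]) for c in clusters for p in c.positions
    )
    return Fingerprint(seq_id=seq_id, entries=entries)


def fingerprint_matrix(
    aln: Alignment,
    clusters: Sequence[ClusterDefinition],
    ref_id: str,
) -> FingerprintMatrix:
    """Fingerprint every row of the alignment against the reference."""
    validate_clusters(clusters)
    pm = build_position_map(aln, ref_id)
    fps = tuple(
        extract_fingerprint(aln, pm, clusters, rid) for rid in aln.ids
    )
    return FingerprintMatrix(clusters=tuple(clusters), fingerprints=fps)


def fingerprint_distance(
    f: Fingerprint,
    g: Fingerprint,
    scope: Iterable[str] | None = None,
) -> int:
    """Hamming distance between fingerprints over the chosen clusters.

    "-" and "X" mismatch every symbol including themselves: a deletion or an
    ambiguous residue never counts as conservation.  ``scope`` restricts the
    count to a subset of cluster names (default: all).
    """
    if f.scaffold() != g.scaffold():
        raise ValueError("fingerprints have different scaffolding")
    names = None if scope is None else set(scope)
    d = 0
    for (c, _, a), (_, _, b) in zip(f.entries, g.entries):
        if names is not None and c not in names:
            continue
        if a != b or a in OPAQUE_SYMBOLS or b in OPAQUE_SYMBOLS:
            d += 1
    return d


# ---------------------------------------------------------------------------
# Cluster configuration (JSON)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterConfig:
    reference_id: str
    clusters: tuple[ClusterDefinition, ...]
    expected_reference_residues: Mapping[int, str] = field(default_factory=dict)


def load_cluster_config(path: str | Path) -> ClusterConfig:
    with Path(path).open() as fh:
        raw = json.load(fh)
    return _config_from_dict(raw)


def _config_from_dict(raw: Mapping) -> ClusterConfig:
    clusters = tuple(
        ClusterDefinition(
            name=c["name"],
            positions=tuple(int(p) for p in c["positions"]),
            role=c.get("role", ""),
        )
        for c in raw["clusters"]
    )
    validate_clusters(clusters)
    expected = {
        int(k): v for k, v in raw.get("expected_reference_residues", {}).items()
    }
    return ClusterConfig(
        reference_id=raw.get("reference_id", ""),
        clusters=clusters,
        expected_reference_residues=expected,
    )


def default_cluster_config() -> ClusterConfig:
    """The packaged default: the five VAO active-site clusters (PsVAO numbering)."""
    raw = json.loads(
        resources.files("asca.data").joinpath("vao_clusters.json").read_text()
    )
    return _config_from_dict(raw)


def validate_reference(
    aln: Alignment, ref_id: str, config: ClusterConfig
) -> list[str]:
    """Warn when the chosen reference disagrees with the expected residues.

    Catches off-by-one numbering mistakes: if the config records which
    residue the reference is expected to carry at each cluster position,
    compare and emit one warning per disagreement.  Returns the messages.
    """
    if not config.expected_reference_residues:
        return []
    pm = build_position_map(aln, ref_id)
    row = aln.row(ref_id)
    messages = []
    for pos, expected in sorted(config.expected_reference_residues.items()):
        if pos > pm.ref_length:
            messages.append(
                f"expected residue at position {pos} but reference "
                f"{ref_id!r} has only {pm.ref_length} residues"
            )
            continue
        actual = row[pm.column(pos)]
        if actual != expected:
            messages.append(
                f"reference {ref_id!r} position {pos}: expected {expected}, "
                f"found {actual}"
            )
    for msg in messages:
        warnings.warn(msg, stacklevel=2)
    return messages


def write_fingerprint_tsv(fm: FingerprintMatrix, path: str | Path) -> None:
    """TSV export: one row per sequence, one column per cluster:position,
    plus a concatenated motif column per cluster."""
    path = Path(path)
    scaffold = fm.fingerprints[0].scaffold() if fm.fingerprints else ()
    pos_cols = [f"{c}:{p}" for c, p in scaffold]
    motif_cols = [f"{c.name}_motif" for c in fm.clusters]
    with path.open("w") as fh:
        fh.write("\t".join(["seq_id", *pos_cols, *motif_cols]) + "\n")
        for fp in fm.fingerprints:
            motifs = [fp.motif(c.name) for c in fm.clusters]
            fh.write("\t".join([fp.seq_id, *fp.symbols(), *motifs]) + "\n")
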
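"""Reference-anchored position mapping and fingerprint extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asca.coordmap import (
    ClusterDefinition,
    Fingerprint,
    build_position_map,
    default_cluster_config,
    extract_fingerprint,
    fingerprint_distance,
    fingerprint_matrix,
    validate_clusters,
    validate_reference,
)
from asca.msa import Alignment
from asca.seqio import AMINO_ACIDS


def linear_scan_map(row: str) -> dict[int, int]:
    """Independent oracle: count non-gaps left to right."""
    out = {}
    k = 0
    for col, ch in enumerate(row):
        if ch != "-":
            k += 1
            out[k] = col
    return out


def random_gapped_alignment(rng, n_rows=3, n_cols=30) -> Alignment:
    rows = []
    for i in range(n_rows):
        chars = rng.choice(list(AMINO_ACIDS), size=n_cols)
        gaps = rng.random(n_cols) < 0.25
        row = "".join("-" if g else c for c, g in zip(chars, gaps))
        if row.count("-") == n_cols:  # keep at least one residue
            row = "M" + row[1:]
        rows.append((f"s{i}", row))
    return Alignment(rows)


def test_position_map_gap_free_is_identity_shift():
    aln = Alignment([("ref", "MKLV")])
    pm = build_position_map(aln, "ref")
    assert pm.pairs == {1: 0, 2: 1, 3: 2, 4: 3}


def test_position_map_single_gap():
    aln = Alignment([("ref", "M-K")])
    pm = build_position_map(aln, "ref")
    assert dict(pm.pairs) == {1: 0, 2: 2}


def test_position_map_matches_linear_scan_oracle():
    rng = np.random.default_rng(17)
    for _ in range(100):
        aln = random_gapped_alignment(rng)
        for rid in aln.ids:
            pm = build_position_map(aln, rid)
            assert dict(pm.pairs) == linear_scan_map(aln.row(rid))
            cols = [pm.pairs[p] for p in sorted(pm.pairs)]
            assert cols == sorted(cols)  # monotone


def test_position_map_missing_reference():
    aln = Alignment([("s1", "MK")])
    with pytest.raises(KeyError, match="nope"):
        build_position_map(aln, "nope")


def _reference_sequence() -> str:
    """A 560-residue sequence carrying the expected residues of the default
    config at their positions, alanine elsewhere."""
    config = default_cluster_config()
    seq = ["A"] * 560
    for pos, sym in config.expected_reference_residues.items():
        seq[pos - 1] = sym
    return "".join(seq)


def test_reference_fingerprints_itself_with_the_documented_residues():
    config = default_cluster_config()
    ref = _reference_sequence()
    aln = Alignment([("PsVAO", ref)])
    pm = build_position_map(aln, "PsVAO")
    fp = extract_fingerprint(aln, pm, config.clusters, "PsVAO")
    a_entries = [e for e in fp.entries if e[0] == "A"]
    assert a_entries == [("A", 316, "L"), ("A", 413, "W"), ("A", 469, "V"), ("A", 470, "C")]
    # every cluster reads back its expected residues
    for cname, pos, sym in fp.entries:
        assert sym == config.expected_reference_residues[pos]
    assert len(fp) == 21
    assert validate_reference(aln, "PsVAO", config) == []


def test_divergent_homolog_shows_the_substituted_states():
    """A gap-free homolog with A at position 424 and E at 470 fingerprints
    as P:424=A and A:470=E (the clade-C6 pattern)."""
    config = default_cluster_config()
    ref = _reference_sequence()
    hom = list(ref)
    hom[424 - 1] = "A"
    hom[470 - 1] = "E"
    aln = Alignment([("PsVAO", ref), ("hom", "".join(hom))])
    pm = build_position_map(aln, "PsVAO")
    fp = extract_fingerprint(aln, pm, config.clusters, "hom")
    by_pos = {p: s for _, p, s in fp.entries}
    assert by_pos[424] == "A"
    assert by_pos[470] == "E"
    # everything else matches the reference
    ref_fp = extract_fingerprint(aln, pm, config.clusters, "PsVAO")
    assert fingerprint_distance(fp, ref_fp) == 2


def test_all_gap_homolog_fingerprint_and_max_distance():
    config = default_cluster_config()
    ref = _reference_sequence()
    aln = Alignment([("PsVAO", ref), ("empty", "-" * 560)])
    pm = build_position_map(aln, "PsVAO")
    fp = extract_fingerprint(aln, pm, config.clusters, "empty")
    assert set(fp.symbols()) == {"-"}
    ref_fp = extract_fingerprint(aln, pm, config.clusters, "PsVAO")
    assert fingerprint_distance(fp, ref_fp) == 21


def test_cluster_position_beyond_reference_raises():
    aln = Alignment([("ref", "MKLV")])
    pm = build_position_map(aln, "ref")
    clusters = [ClusterDefinition("A", (2, 9))]
    with pytest.raises(ValueError, match="9"):
        extract_fingerprint(aln, pm, clusters, "ref")


def test_overlapping_clusters_rejected():
    with pytest.raises(ValueError, match="position 3"):
        validate_clusters(
            [ClusterDefinition("A", (1, 3)), ClusterDefinition("B", (3, 5))]
        )


def test_clade_c6_pattern_distance_is_five_with_l468_reference():
    """Planting the five C6-pattern states (61F, 409E, 424A, 468I, 470E)
    against a reference carrying L468 gives distance 5 over all clusters."""
    config = default_cluster_config()
    ref = list(_reference_sequence())
    ref[468 - 1] = "L"
    hom = list(ref)
    for pos, sym in {61: "F", 409: "E", 424: "A", 468: "I", 470: "E"}.items():
        hom[pos - 1] = sym
    aln = Alignment([("ref", "".join(ref)), ("hom", "".join(hom))])
    fm = fingerprint_matrix(aln, config.clusters, "ref")
    # direct per-position comparison oracle
    expected = sum(
        a != b for a, b in zip(fm.get("ref").symbols(), fm.get("hom").symbols())
    )
    assert expected == 5
    assert fingerprint_distance(fm.get("hom"), fm.get("ref")) == 5


def test_fingerprint_matrix_trivial_and_planted(default_run):
    config = default_cluster_config()
    ref = _reference_sequence()
    one = fingerprint_matrix(Alignment([("PsVAO", ref)]), config.clusters, "PsVAO")
    assert len(one.fingerprints) == 1
    two = fingerprint_matrix(
        Alignment([("PsVAO", ref), ("copy", ref)]), config.clusters, "PsVAO"
    )
    assert two.get("PsVAO").symbols() == two.get("copy").symbols()
    # planted truth from the simulated scenario: every fingerprint correct
    family, result = default_run
    for fp in result.fingerprints.fingerprints:
        truth = family.planted_fingerprints[fp.seq_id]
        assert {p: s for _, p, s in fp.entries} == truth


def test_gap_only_columns_do_not_change_fingerprints():
    config = default_cluster_config()
    ref = _reference_sequence()
    hom = ref[:200] + ref[210:]  # deletion elsewhere
    base = Alignment([("PsVAO", ref), ("hom", ref[:200] + "-" * 10 + hom[200:])])
    base_fm = fingerprint_matrix(base, config.clusters, "PsVAO")
    # insert a gap-only column block at the front
    padded = Alignment(
        [(rid, "---" + row) for rid, row in base.rows]
    )
    padded_fm = fingerprint_matrix(padded, config.clusters, "PsVAO")
    for a, b in zip(base_fm.fingerprints, padded_fm.fingerprints):
        assert a.symbols() == b.symbols()


scaffold = tuple(("A", p) for p in range(1, 9))
symbols_st = st.lists(
    st.sampled_from(AMINO_ACIDS), min_size=8, max_size=8
)


def _fp(name, syms):
    return Fingerprint(
        seq_id=name, entries=tuple((c, p, s) for (c, p), s in zip(scaffold, syms))
    )


@settings(max_examples=100, derandomize=True, deadline=None)
@given(symbols_st, symbols_st, symbols_st)
def test_fingerprint_distance_is_a_metric_on_residue_symbols(sa, sb, sc):
    f, g, h = _fp("f", sa), _fp("g", sb), _fp("h", sc)
    assert fingerprint_distance(f, f) == 0
    assert fingerprint_distance(f, g) == fingerprint_distance(g, f)
    assert (
        fingerprint_distance(f, h)
        <= fingerprint_distance(f, g) + fingerprint_distance(g, h)
    )


def test_gap_and_x_mismatch_everything_including_themselves():
    f = _fp("f", ["-", "X", "A", "A", "A", "A", "A", "A"])
    g = _fp("g", ["-", "X", "A", "A", "A", "A", "A", "A"])
    assert fingerprint_distance(f, g) == 2


def test_distance_scope_restriction():
    config = default_cluster_config()
    ref = _reference_sequence()
    other = list(ref)
    for pos in (316, 413, 469, 470, 61):  # four A-cluster changes + one H
        other[pos - 1] = "G"
    aln = Alignment([("ref", ref), ("o", "".join(other))])
    fm = fingerprint_matrix(aln, config.clusters, "ref")
    d = fingerprint_distance(fm.get("o"), fm.get("ref"), scope={"A"})
    assert d == 4  # bounded by the A-cluster size


def test_scaffold_mismatch_raises():
    f = _fp("f", ["A"] * 8)
    g = Fingerprint(seq_id="g", entries=(("B", 1, "A"),))
    with pytest.raises(ValueError, match="scaffold"):
        fingerprint_distance(f, g)
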
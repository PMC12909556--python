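"""Build the neighbor-joining tree, root it on the outgroup, cut clades.

Reads the alignment from results/02_alignment/, computes p-distances, runs
neighbor joining, roots on the bacterial-style outgroup (BO_*), and cuts the
6 longest internal ingroup branches to recover 7 clades.  Reports whether
the recovered partition equals the planted one.
"""

from pathlib import Path

from asca.msa import read_alignment
from asca.phylo import (
    extract_clades,
    neighbor_joining,
    p_distance_matrix,
    root_with_outgroup,
    write_newick,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    aln = read_alignment(ROOT / "results" / "02_alignment" / "family.afa")
    out = ROOT / "results" / "03_tree"
    out.mkdir(parents=True, exist_ok=True)

    dm = p_distance_matrix(aln)
    dm.write_tsv(out / "distances.tsv")
    tree = neighbor_joining(dm)
    outgroup = [rid for rid in aln.ids if rid.startswith("BO_")]
    rooted = root_with_outgroup(tree, outgroup)
    write_newick(rooted, out / "tree.nwk")
    print(f"NJ tree on {len(aln)} leaves, rooted on outgroup {outgroup}")

    clades = extract_clades(rooted, k=7, outgroup_ids=outgroup)
    with (out / "clades.tsv").open("w") as fh:
        fh.write("seq_id\tclade\n")
        for label in sorted(clades):
            for sid in sorted(clades[label]):
                fh.write(f"{sid}\t{label}\n")

    truth_lines = (
        ROOT / "results" / "01_simulated" / "truth_membership.tsv"
    ).read_text().splitlines()[1:]
    truth: dict[str, set[str]] = {}
    for line in truth_lines:
        sid, clade = line.split("\t")
        if clade != "BO":
            truth.setdefault(clade, set()).add(sid)
    recovered = {frozenset(v) for v in clades.values()}
    planted = {frozenset(v) for v in truth.values()}
    print(f"recovered {len(clades)} clades; "
          f"partition matches planted clades: {recovered == planted}")
    for label in sorted(clades):
        members = sorted(clades[label])
        source = sorted({m.split('_')[0] for m in members})
        print(f"  {label}: {len(members)} members from {source}")


if __name__ == "__main__":
    main()
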
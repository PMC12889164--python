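"""Sequence and structure similarity across the protein divergence ladder.

For each generated protein pair: global alignment (similarity/identity %),
average Cα lDDT from the written PDB files, and alignment coverage — the
same metrics the screening stage consumes.

Reads results/synthetic/structures/, writes results/structure/pair_metrics.tsv.
"""

from pathlib import Path

import pandas as pd

from hnscreen.align import global_align, read_fasta
from hnscreen.structure import average_lddt, coverage, read_ca_coords

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    struct_dir = ROOT / "synthetic" / "structures"
    rows = []
    for fasta in sorted(struct_dir.glob("pair*.fasta")):
        pair_id = fasta.stem
        rice, human = read_fasta(fasta)
        aln = global_align(rice, human)
        ref = read_ca_coords(struct_dir / f"{pair_id}_rice.pdb")
        mod = read_ca_coords(struct_dir / f"{pair_id}_human.pdb")
        mapping = [(i, i) for i in range(min(ref.length, mod.length))]
        lddt = average_lddt(ref, mod, mapping)
        qcov, tcov = coverage(mapping, rice.length, human.length)
        rows.append(
            {
                "pair_id": pair_id,
                "identity_pct": round(aln.identity_pct, 2),
                "similarity_pct": round(aln.similarity_pct, 2),
                "avg_lddt": round(lddt, 4),
                "qcov": qcov,
                "tcov": tcov,
            }
        )
        print(f"{pair_id}: similarity {aln.similarity_pct:.1f}%, identity "
              f"{aln.identity_pct:.1f}%, avg lDDT {lddt:.3f}")

    out = ROOT / "structure"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "pair_metrics.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
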
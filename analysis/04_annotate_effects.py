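#!/usr/bin/env python
"""Annotate the retained variants against the gene models and tabulate the
category marginals (nonSyn/Syn/splice/intron/UTR5/UTR3/intergenic for SNPs;
frameshift/nonframeshift/splice/... for InDels).

Findings: the partition identity holds (category counts sum to the total per
class) and the functional counts equal nonSyn+splice (SNPs) and
frameshift+nonframeshift+splice (InDels).
"""

from pathlib import Path

import pandas as pd

from brassica_variome import annotate as ann, io as vio, varfilter

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    if not (RUN / "matrix.tsv").exists():
        raise SystemExit("run analysis/03_filter_variants.py first")
    matrix = vio.read_matrix(RUN / "matrix.tsv")
    ref = vio.read_fasta(RUN / "genome.fa")
    genes = vio.read_gff3(RUN / "genes.gff3")

    annotated = ann.annotate(varfilter.matrix_variants(matrix), genes, ref)
    vio.write_tsv(annotated, RUN / "annotated.tsv")
    marginals = ann.marginal_counts(annotated)
    table = pd.DataFrame(
        [
            {"vclass": vclass, "category": str(cat), "count": int(n)}
            for vclass, series in marginals.items()
            for cat, n in series.items()
        ]
    )
    vio.write_tsv(table, RESULTS / "04_category_marginals.tsv")

    f = ann.functional_counts(annotated)
    print(table.pivot(index="vclass", columns="category", values="count").to_string())
    print(f"\nfunctional SNPs (nonSyn + splice): {f['SNP']} "
          f"= {marginals['SNP']['nonSyn']} + {marginals['SNP']['splice']}")
    print(f"functional InDels (frameshift + nonframeshift + splice): {f['InDel']} "
          f"= {marginals['InDel']['frameshift']} + {marginals['InDel']['nonframeshift']}"
          f" + {marginals['InDel']['splice']}")
    for vclass in ("SNP", "InDel"):
        m = marginals[vclass]
        assert m["total"] == m.drop("total").sum()
    print("partition identity holds for both classes")


if __name__ == "__main__":
    main()
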
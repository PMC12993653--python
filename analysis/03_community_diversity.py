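"""Community diversity: alpha metrics, unweighted UniFrac, PCoA, the
full-factorial PERMANOVA (treatment, time, microhabitat and interactions),
beta dispersion across treatments, and the pretreatment-vs-ambient time
comparison per phylum.  Writes per-community tables under results/diversity/.
"""

from pathlib import Path

import pandas as pd

from rhizosignal import diversity as dv
from rhizosignal import io

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "diversity"

FORMULA = ("treatment + timepoint + microhabitat + treatment:timepoint"
           " + treatment:microhabitat + timepoint:microhabitat"
           " + treatment:timepoint:microhabitat")


def main() -> None:
    for name in ("prok", "fungi"):
        out = OUT / name
        out.mkdir(parents=True, exist_ok=True)
        table = io.read_count_table(DATA / name / "counts_rarefied.tsv")
        tree = io.read_tree(DATA / name / "tree.nwk")
        meta = io.read_metadata(DATA / name / "metadata.tsv")
        taxonomy = io.read_taxonomy(DATA / name / "taxonomy.tsv")

        alpha = dv.alpha_diversity(table, tree)
        alpha.to_csv(out / "alpha.tsv", sep="\t")

        dm = dv.unweighted_unifrac(table, tree)
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out / "unifrac.tsv", sep="\t")
        dv.pcoa(dm).axes(4).to_csv(out / "pcoa.tsv", sep="\t")

        perm = dv.permanova(dm, meta, FORMULA, n_perm=999, seed=2)
        perm.table.to_csv(out / "permanova.tsv", sep="\t")

        disp = dv.beta_dispersion(dm, meta.table["treatment"], n_perm=999, seed=3)
        disp.distances.to_frame().assign(
            F=disp.f_statistic, p_value=disp.p_value
        ).to_csv(out / "dispersion.tsv", sep="\t")

        tc = dv.time_comparison(table, meta, taxonomy, rank="phylum")
        tc.to_csv(out / "time_comparison.tsv", sep="\t")

        t = perm.table
        print(f"\n== {name} ==")
        print(f"treatment: F={t.loc['treatment','pseudo_F']:.2f} "
              f"R²={t.loc['treatment','r2']:.4f} p={t.loc['treatment','p_value']:.3f}")
        print(f"beta dispersion across treatments: F={disp.f_statistic:.2f} "
              f"p={disp.p_value:.3f}")
        sig_tc = tc[tc["p_adjusted"] < 0.05] if len(tc) else tc
        print(f"phyla shifted between T1 and ambient-T2 (BH q<0.05): "
              f"{list(sig_tc.index) if len(sig_tc) else 'none'}")


if __name__ == "__main__":
    main()
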
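"""Root exudates vs community composition: envfit of each compound onto the
first two PCoA axes, Mantel correlation between UniFrac and exudate-profile
distances, exhaustive best-subset (bioenv-style) search for the compound set
maximising the Mantel correlation, and Pearson correlations between the
responding clades' relative abundances and individual compounds.
"""

from pathlib import Path

import pandas as pd
from skbio import DistanceMatrix

from rhizosignal import diversity as dv
from rhizosignal import exudates as ex
from rhizosignal import io

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "exudates"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    name = "prok"  # exudates are coupled to the prokaryotic ordination
    table = io.read_count_table(DATA / name / "counts_rarefied.tsv")
    tree = io.read_tree(DATA / name / "tree.nwk")
    meta = io.read_metadata(DATA / name / "metadata.tsv")
    taxonomy = io.read_taxonomy(DATA / name / "taxonomy.tsv")
    exu = io.read_exudates(DATA / name / "exudates.tsv")

    t2r = [s for s in meta.select(timepoint="T2", microhabitat="rhizosphere")
           if s in exu.index]
    dm = dv.unweighted_unifrac(table.select_samples(t2r), tree)

    fit = ex.envfit(dv.pcoa(dm).axes(2), exu.loc[t2r], n_perm=999, seed=9)
    fit.to_csv(OUT / "envfit.tsv", sep="\t")

    mres = ex.mantel(dm, ex.exudate_distance(exu.loc[t2r]), n_perm=999, seed=10)
    pd.DataFrame([mres.__dict__]).to_csv(OUT / "mantel.tsv", sep="\t", index=False)

    subsets = ex.best_subset(dm, exu.loc[t2r], max_subset_size=4, n_perm=999, seed=11)
    subsets_out = subsets.assign(subset=subsets["subset"].map(lambda c: ",".join(c)))
    subsets_out.to_csv(OUT / "subsets.tsv", sep="\t", index=False)

    # clade abundances (class level) vs compounds
    agg = io.aggregate_to_rank(table.select_samples(t2r), taxonomy, rank="class")
    rel = io.to_relative_abundance(agg).T  # samples × classes
    corr = ex.clade_exudate_correlation(rel, exu.loc[t2r])
    corr.to_csv(OUT / "clade_exudate.tsv", sep="\t", index=False)

    print(f"Mantel (all compounds): r={mres.r:.3f} r²={mres.r_squared:.3f} "
          f"p={mres.p_value:.3f}")
    top = subsets_out.iloc[0]
    print(f"best subset: {{{top['subset']}}} with Mantel r={top['mantel_r']:.3f} "
          f"(p={top['p_value']:.3f})")
    sig_fit = fit[fit["p_adjusted"] < 0.05]
    print(f"compounds with significant envfit (BH q<0.05): {list(sig_fit.index)}")
    n_sig_corr = int(corr["significant"].sum()) if len(corr) else 0
    print(f"clade × compound Pearson correlations with BH q<0.05: {n_sig_corr}")


if __name__ == "__main__":
    main()
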
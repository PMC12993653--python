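"""Cross-kingdom differential association networks: both communities are
aggregated to class level, concatenated sample-wise, SparCC networks are
estimated per treatment group, and the top-50 candidate edges are
permutation-tested for drought-vs-ambient differences (mild and severe).
"""

from pathlib import Path

import pandas as pd

from rhizosignal import io
from rhizosignal import network as nw

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "network"


def main() -> None:
    meta = io.read_metadata(DATA / "prok" / "metadata.tsv")
    agg = []
    for name in ("prok", "fungi"):
        table = io.read_count_table(DATA / name / "counts_rarefied.tsv")
        taxonomy = io.read_taxonomy(DATA / name / "taxonomy.tsv")
        agg.append(nw.aggregate_to_rank(table, taxonomy, rank="class", kingdom=name))
    samples = agg[0].sample_ids
    merged_df = pd.concat([t.to_dataframe()[samples] for t in agg])
    merged = io.CountTable(list(merged_df.index), samples, merged_df.to_numpy())
    print(f"cross-kingdom class table: {merged.n_taxa} classes × {merged.n_samples} samples")

    for contrast in ("mild", "severe"):
        out = OUT / contrast
        out.mkdir(parents=True, exist_ok=True)
        edges, net1, net2 = nw.differential_network(
            merged, meta, (contrast, "ambient"), k=50, n_perm=500, seed=8,
        )
        net1.to_dataframe().to_csv(out / f"net_{contrast}.tsv", sep="\t")
        net2.to_dataframe().to_csv(out / "net_ambient.tsv", sep="\t")
        nw.write_edge_list(edges, out / "diffnet.tsv")
        nw.write_edge_list(edges, out / "diffnet.dot", dot=True)
        sig = [e for e in edges if e.p_adjusted < 0.05]
        patterns = pd.Series([e.sign_pattern for e in edges]).value_counts()
        print(f"\n{contrast}-vs-ambient: {len(edges)} candidate edges, "
              f"{len(sig)} with BH q<0.05")
        print(patterns.to_string())


if __name__ == "__main__":
    main()
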
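"""Drought response ratios per ZOTU with a 999-permutation null, clade-wide
one-sample t-tests (BH-corrected) at phylum and class level, and iTOL
colour-strip exports of the positive/negative/neutral calls — for the mild
and the severe contrast in both communities.
"""

from pathlib import Path

import pandas as pd

from rhizosignal import io
from rhizosignal import response as rs

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "response"

COLORS = {"positive": "#d62728", "negative": "#e8c21c", "neutral": "#aaaaaa"}


def main() -> None:
    for name in ("prok", "fungi"):
        table = io.read_count_table(DATA / name / "counts_rarefied.tsv")
        taxonomy = io.read_taxonomy(DATA / name / "taxonomy.tsv")
        meta = io.read_metadata(DATA / name / "metadata.tsv")
        for contrast in ("mild", "severe"):
            out = OUT / name / contrast
            out.mkdir(parents=True, exist_ok=True)
            rr = rs.response_ratio_null(
                table, meta, (contrast, "ambient"), n_perm=999, seed=4
            )
            rr.table.to_csv(out / "rr.tsv", sep="\t")
            frames = []
            for rank in ("phylum", "class"):
                ct = rs.clade_response_test(rr, taxonomy, rank=rank)
                ct.insert(0, "rank", rank)
                frames.append(ct)
            clades = pd.concat(frames)
            clades.to_csv(out / "clade_tests.tsv", sep="\t")
            calls, _ = rs.call_directions(rr, clades)
            io.export_itol_colorstrip(
                calls.to_dict(), COLORS, f"RR_{name}_{contrast}",
                path=out / "itol_strip.txt",
            )
            n_pos = (calls == "positive").sum()
            n_neg = (calls == "negative").sum()
            sig = clades[clades["direction"] != "none"]
            print(
                f"{name}/{contrast}-vs-ambient: {n_pos} ZOTUs up, {n_neg} down "
                f"(permutation p<0.05); clades with coherent response: "
                f"{[(r, i, d) for r, i, d in zip(sig['rank'], sig.index, sig['direction'])]}"
            )


if __name__ == "__main__":
    main()
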
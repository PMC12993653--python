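"""Prepare the count tables for analysis: drop banned lineages (none are
planted by the generator, so this is a no-op pass that exercises the filter)
and rarefy every sample to the depth of the shallowest one, per community.
"""

from pathlib import Path

from rhizosignal import io

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    for name in ("prok", "fungi"):
        table = io.read_count_table(DATA / name / "counts.tsv")
        taxonomy = io.read_taxonomy(DATA / name / "taxonomy.tsv")
        banned = {"chloroplast"} if name == "prok" else {
            "animalia", "protozoa", "viridiplantae"
        }
        table = io.filter_by_taxonomy(table, taxonomy, banned)
        rare = io.rarefy(table, depth="min", seed=1)
        io.write_count_table(rare, DATA / name / "counts_rarefied.tsv")
        print(
            f"{name}: kept {table.n_taxa} taxa, rarefied {rare.n_samples} "
            f"samples to {int(rare.sample_sums[0])} reads each"
        )


if __name__ == "__main__":
    main()
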
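#!/usr/bin/env python
"""Run the full response-intensity campaign and tabulate the outcomes.

Covers the four named conditions (no toxicity; equal, predator-dominant and
prey-dominant response strength at levels 0.1 / 1.0 / 10.0) plus the
feeding-decline variants. Writes the per-scenario summary table as CSV and the
full YAML summary document under results/.
"""

from pathlib import Path

from mplv import paper_campaign, run_campaign
from mplv.io import write_summary

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    result = run_campaign(paper_campaign())
    df = result.to_dataframe()
    df.to_csv(OUT / "campaign_summary.csv", index=False)
    write_summary(result, OUT / "campaign_summary.yaml")

    print(df.to_string(index=False))
    print()
    n_coexist = (df.outcome == "coexistence").sum()
    print(f"{n_coexist}/{len(df)} scenarios coexist over the 10-month window.")
    print("Weak intensities (0.1, 0.1) barely perturb the toxin-free cycle;")
    print("equal middle intensities doom the predator; severe intensities")
    print("collapse both species, the predator always first.")
    print(f"wrote {OUT}/campaign_summary.csv and campaign_summary.yaml")


if __name__ == "__main__":
    main()
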
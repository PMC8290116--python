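#!/usr/bin/env python
"""Generate the synthetic study inputs with planted truth.

Writes the truth tables (small) under results/ and the bulky raw inputs
(per-species PAF, window tables, site tables) under scratch/, where the
downstream drivers read them.
"""

from pathlib import Path

import pandas as pd

from cladesv import alignment_io as aio
from cladesv import scenarios

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "inputs"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    records, cmap, truth, gi = scenarios.inversion_scenario(SEED)
    n_records = 0
    for sp, recs in records.items():
        aio.write_paf(recs, SCRATCH / f"{sp}.paf")
        n_records += len(recs)
    with open(SCRATCH / "ref.fai", "w") as fh:
        for name, length in cmap.chromosomes.items():
            fh.write(f"{name}\t{length}\n")
    pd.DataFrame(truth.inversions).to_csv(RESULTS / "truth_inversions.tsv", sep="\t", index=False)

    windows, cov_truth = scenarios.coverage_scenario(SEED)
    aio.write_window_table(windows, SCRATCH / "windows.tsv")
    pd.DataFrame(cov_truth.amplifications).to_csv(
        RESULTS / "truth_amplifications.tsv", sep="\t", index=False
    )

    sites, site_truth = scenarios.introgression_scenario(SEED)
    aio.write_site_table(sites, SCRATCH / "sites.tsv")
    pd.DataFrame(site_truth.tracts).to_csv(RESULTS / "truth_tracts.tsv", sep="\t", index=False)

    print(f"simulated {len(records)} species, {n_records} filtered alignments")
    print(f"planted {len(truth.inversions)} inversions, "
          f"{len(cov_truth.amplifications)} amplifications "
          f"({sum(a['truth'] for a in cov_truth.amplifications)} true), "
          f"{len(site_truth.tracts)} introgressed tract(s)")
    print(f"coverage windows: {len(windows)}; sites: {len(sites)}")
    print(f"raw inputs under {SCRATCH}, truth tables under {RESULTS}")


if __name__ == "__main__":
    main()
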
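#!/usr/bin/env python
"""Pseudogenization screen on simulated exon copies.

Generates exon-copy families with planted edits (synonymous /
nonsynonymous changes, internal stops, assembly N-runs), runs the
hygiene rules + stop scan + Li-1993 Ka/Ks, and summarizes the screen the
way it would be read on real data: what fraction of copies carry stops,
and whether Ka/Ks separates constrained from unconstrained copies.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cladesv import selection_screen as sel
from cladesv import synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    n_exons = 40
    copies_per_exon = 8
    stop_frac = 0.12  # planted stop-carrying fraction of copies
    for e in range(n_exons):
        ref = sd.make_reference_cds(100, seed=SEED * 1000 + e)
        for c in range(copies_per_exon):
            kind = "stop" if rng.random() < stop_frac else ("n_run" if rng.random() < 0.05 else "clean")
            copy, _ = sd.mutate_codons(
                ref,
                n_syn=int(rng.integers(1, 5)),
                n_nonsyn=int(rng.integers(0, 2)),
                n_stops=1 if kind == "stop" else 0,
                n_run=kind == "n_run",
                seed=SEED * 100_000 + e * 100 + c,
            )
            aln = sel.prepare_copy(copy, ref, exon=f"exon{e:03d}", copy_id=f"copy{c}")
            row = {"exon": aln.exon, "copy": aln.copy_id, "excluded": aln.excluded_reason or ""}
            if aln.excluded_reason is None:
                n_stops, _ = sel.scan_stop_codons(aln)
                res = sel.kaks_li93(aln)
                row.update({"n_stops": n_stops, "Ka": res.Ka, "Ks": res.Ks, "ratio": res.ratio})
            rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "selection_screen.tsv", sep="\t", index=False)

    scanned = table[table["excluded"] == ""]
    stop_pct = 100.0 * (scanned["n_stops"] > 0).mean()
    ratios = scanned["ratio"].dropna()
    print(f"{len(table)} exon copies screened; {len(table) - len(scanned)} excluded by hygiene rules")
    print(f"{stop_pct:.1f}% of scanned copies carry an internal stop codon "
          f"(planted rate {100 * stop_frac:.0f}%)")
    print(f"median Ka/Ks of stop-free copies: {ratios.median():.3f} "
          "(constrained copies sit well below 1)")

    # rate-ratio recovery under known omega
    for omega in (0.1, 1.0):
        vals = []
        for rep in range(100):
            ref, copy = sd.evolve_codon_pair(300, omega, n_events=60, seed=SEED * 7919 + rep)
            res = sel.kaks_li93(sel.CodonAlignment(ref=ref, copy=copy))
            if res.ratio is not None:
                vals.append(res.ratio)
        print(f"omega {omega}: median estimated Ka/Ks = {np.median(vals):.3f} over {len(vals)} pairs")


if __name__ == "__main__":
    main()
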
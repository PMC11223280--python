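"""Three-group permutation inference on connectivity and topology.

Omnibus permutation test per (parameter, band, region); pairwise tests
(Bonferroni-corrected, factor 3) only where the omnibus test rejects.
Writes results/stats.tsv and prints the band-level decision pattern.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import ALPHA_LEVEL, N_PERM, RESULTS, SEED

from eegfc.group_stats import compare_all, comparisons_frame


def main() -> None:
    table = pd.read_csv(RESULTS / "metrics.tsv", sep="\t")
    results = compare_all(table, alpha=ALPHA_LEVEL, n_perm=N_PERM, seed=SEED)
    frame = comparisons_frame(results)
    out = RESULTS / "stats.tsv"
    frame.to_csv(out, sep="\t", index=False)
    print(f"wrote {len(frame)} comparisons to {out}\n")

    for r in results:
        if r.region != "whole_brain" or not r.parameter.startswith("mean_"):
            continue
        verdicts = {k: ("*" if p < ALPHA_LEVEL else "ns") for k, p in r.pairwise_p.items()}
        print(f"{r.band} {r.parameter}: omnibus p={r.omnibus_p:.4f}, "
              f"group means {dict((g, round(v, 4)) for g, v in r.group_means.items())}")
        if r.pairwise_p:
            print(f"  corrected pairwise: "
                  + ", ".join(f"{k} p={r.pairwise_p[k]:.4f} ({verdicts[k]})"
                              for k in sorted(r.pairwise_p)))
    n_sig = sum(1 for r in results if r.omnibus_p < ALPHA_LEVEL)
    print(f"\n{n_sig}/{len(results)} comparisons omnibus-significant at {ALPHA_LEVEL}")


if __name__ == "__main__":
    main()
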
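"""Threshold connectivity into binary networks and compute graph metrics.

One threshold per band by the no-isolated-node rule (per-subject
minimum, so no subject's network has an isolated node), then the five
whole-brain parameters plus regional means.  Writes networks to
results/networks and the tidy metrics table to results/metrics.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import BANDS, MATRIX_DIR, NETWORK_DIR, RESULTS

from eegfc.connectivity import mean_connectivity
from eegfc.graphnet import band_threshold, binarize, compute_metrics, metrics_table
from eegfc.io import read_connectivity, write_network


def main() -> None:
    frames = []
    for band_name in BANDS:
        paths = sorted(MATRIX_DIR.glob(f"*_{band_name}_*.tsv"))
        mats = [read_connectivity(p) for p in paths if not p.stem.startswith("group_")]
        thr = band_threshold(mats, "per_subject_min")
        print(f"{band_name}: no-isolated-node threshold = {thr:.4f} over {len(mats)} subjects")
        rows = []
        for m in mats:
            net = binarize(m, thr, validate=True)
            write_network(net, NETWORK_DIR)
            rows.append((net, compute_metrics(net)))
        frames.append(metrics_table(rows))
        frames.append(pd.DataFrame.from_records([
            {"subject": m.subject_id, "group": m.group, "band": band_name,
             "parameter": f"mean_{m.metric}", "region": "whole_brain",
             "value": mean_connectivity(m)}
            for m in mats
        ]))
    table = pd.concat(frames, ignore_index=True)
    out = RESULTS / "metrics.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.6g")
    whole = table[table.region == "whole_brain"]
    print(whole.pivot_table(index=["band", "parameter"], columns="group",
                            values="value").round(4).to_string())
    print(f"wrote {len(table)} metric rows to {out}")


if __name__ == "__main__":
    main()
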
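"""Estimate band-specific connectivity for every subject.

Theta uses the phase lag index (PLI), alpha the leakage-corrected
amplitude envelope correlation (AEC-c); 12.288-s epochs with 50%
overlap, estimates averaged across epochs.  Writes per-subject and
group-average matrices to results/connectivity.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import BANDS, MATRIX_DIR, STUDY_DIR

from eegfc.connectivity import aecc_matrix, group_average, mean_connectivity, pli_matrix
from eegfc.io import read_study, write_connectivity
from eegfc.pipeline import DEFAULT_METRIC_ROUTING
from eegfc.signal_prep import BANDS as BAND_DEFS, bandpass, epoch


def main() -> None:
    recs = read_study(STUDY_DIR)
    for band_name in BANDS:
        band = BAND_DEFS[band_name]
        metric = DEFAULT_METRIC_ROUTING[band_name]
        mats = []
        for rec in recs:
            ep = epoch(bandpass(rec, band), band)
            m = pli_matrix(ep) if metric == "PLI" else aecc_matrix(ep)
            write_connectivity(m, MATRIX_DIR)
            mats.append(m)
        print(f"{band_name} ({metric}): {len(mats)} subject matrices")
        for group in ("AD", "FTD", "HC"):
            sub = [m for m in mats if m.group == group]
            ga = group_average(sub)
            ga.subject_id = f"group_{group}"
            write_connectivity(ga, MATRIX_DIR)
            print(f"  {group}: mean {metric} = {mean_connectivity(ga):.4f}")


if __name__ == "__main__":
    main()
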
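"""Shared design of the synthetic three-group study driven by the
numbered analysis scripts.

Emulates the clinical design (AD, FTD, HC; 19-channel 10-20 montage)
with planted theta hyperconnectivity and alpha hypoconnectivity in both
patient groups, scaled down (250 Hz, 31 s/subject, 12/group) so the
whole script sequence runs in a few minutes on one CPU.
"""

from pathlib import Path

from eegfc.synth import SyntheticStudySpec

_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"  # small final tables only
SCRATCH = _ROOT / "scratch"  # bulky intermediates (signals, matrices, networks)
STUDY_DIR = SCRATCH / "study"
MATRIX_DIR = SCRATCH / "connectivity"
NETWORK_DIR = SCRATCH / "networks"

SEED = 20240901
BANDS = ("theta", "alpha")
N_PERM = 5000
ALPHA_LEVEL = 0.05

STUDY_SPEC = SyntheticStudySpec(
    n_subjects_per_group=(12, 12, 12),
    group_labels=("AD", "FTD", "HC"),
    fs=250.0,
    duration_s=31.0,
    bands=BANDS,
    seed=SEED,
    band_effects={
        ("AD", "theta"): 2.0, ("FTD", "theta"): 2.0,
        ("AD", "alpha"): 0.25, ("FTD", "alpha"): 0.25,
    },
)
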
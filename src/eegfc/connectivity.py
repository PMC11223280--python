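"""Pairwise coupling estimates: PLI and leakage-corrected AEC.

The phase lag index (PLI) summarizes the asymmetry of the instantaneous
phase-difference distribution, ``PLI = |<sign(sin dphi(t_k))>|``.  It is
blind to zero-lag coupling: volume conduction, which spreads one source
across electrodes with no time lag, cannot raise it.

The amplitude envelope correlation (AEC) is the Pearson correlation of
the two Hilbert envelopes.  Its leakage-corrected variant (AEC-c) first
removes the zero-lag component by pairwise orthogonalization (each
signal regressed on the other), estimated here symmetrically: both
orthogonalization directions are computed, each envelope correlation is
taken in absolute value, and the two are averaged, giving a value in
[0, 1].

Per-subject matrices are estimated per epoch and averaged across epochs;
a small fraction of each epoch edge is trimmed before estimation to
suppress Hilbert edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from eegfc.errors import ConfigurationError, DataError, DegenerateInputError
from eegfc.signal_prep import (
    EDGE_TRIM_FRACTION,
    BandDefinition,
    EpochedRecording,
    trim_edges,
)

METRICS = ("PLI", "AEC", "AEC_c")


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel coupling strengths for one subject/band."""

    values: np.ndarray
    metric: str
    band: BandDefinition
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    group: str = ""
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise DataError("connectivity matrix must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def pli(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase lag index of two instantaneous-phase series.

    ``|mean(sign(sin(phase_x - phase_y)))|``; samples where the phase
    difference is an exact multiple of pi contribute zero.  1 means a
    constant nonzero lag, 0 means no nonzero-lag coupling.
    """
    px = np.asarray(phase_x, dtype=float)
    py = np.asarray(phase_y, dtype=float)
    if px.shape != py.shape:
        raise DataError(f"phase series length mismatch: {px.shape} vs {py.shape}")
    if px.size < 2:
        raise DataError("need at least 2 samples for PLI")
    return float(np.abs(np.mean(np.sign(np.sin(px - py)))))


def _epoch_phases(ep: EpochedRecording, edge_trim: float) -> np.ndarray:
    """Instantaneous phases, epoch x channel x sample, edge-trimmed."""
    z = hilbert(ep.epochs, axis=-1)
    return trim_edges(np.angle(z), edge_trim, axis=-1)


def pli_matrix(ep: EpochedRecording, edge_trim: float = EDGE_TRIM_FRACTION) -> ConnectivityMatrix:
    """Per-subject PLI matrix: PLI per channel pair per epoch, mean across epochs."""
    if ep.n_epochs < 1:
        raise DataError(f"subject {ep.subject_id!r}: no epochs")
    phases = _epoch_phases(ep, edge_trim)  # (n_ep, n_ch, n_s)
    # sign(sin(phi_i - phi_j)) for all ordered pairs, vectorized per epoch
    n_ep, n_ch, _ = phases.shape
    mats = np.empty((n_ep, n_ch, n_ch))
    for e in range(n_ep):
        d = phases[e, :, None, :] - phases[e, None, :, :]
        mats[e] = np.abs(np.mean(np.sign(np.sin(d)), axis=-1))
    values = mats.mean(axis=0)
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # exact symmetry against fp noise
    return ConnectivityMatrix(
        values=values,
        metric="PLI",
        band=ep.band,
        channel_labels=ep.channel_labels,
        subject_id=ep.subject_id,
        group=ep.group,
        n_epochs_averaged=n_ep,
    )


def orthogonalize(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove from ``x`` its least-squares projection onto ``y``.

    The regression uses mean-centered series, so the residual has exactly
    zero sample (Pearson) correlation with ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("orthogonalize: length mismatch")
    yc = y - y.mean()
    denom = float(yc @ yc)
    if denom <= np.finfo(float).tiny * max(x.size, 1):
        raise DegenerateInputError("orthogonalize: regressor is (near-)constant")
    beta = float((x - x.mean()) @ yc) / denom
    return x - beta * y


def aec(env_x: np.ndarray, env_y: np.ndarray) -> float:
    """Pearson correlation of two amplitude-envelope series."""
    ex = np.asarray(env_x, dtype=float)
    ey = np.asarray(env_y, dtype=float)
    if ex.shape != ey.shape:
        raise DataError("aec: length mismatch")
    if ex.size < 3:
        raise DataError("aec: need at least 3 samples")
    if np.ptp(ex) == 0 or np.ptp(ey) == 0:
        raise DegenerateInputError("aec: constant envelope has undefined correlation")
    return float(np.corrcoef(ex, ey)[0, 1])


def _envelope(x: np.ndarray, edge_trim: float) -> np.ndarray:
    return trim_edges(np.abs(hilbert(np.asarray(x, dtype=float))), edge_trim)


def aec_c(
    x: np.ndarray,
    y: np.ndarray,
    edge_trim: float = EDGE_TRIM_FRACTION,
    use_abs: bool = True,
    log_env: bool = False,
) -> float:
    """Leakage-corrected AEC of two band-filtered signals (symmetric).

    Averages ``|corr(env(x|y), env(y))|`` and ``|corr(env(y|x), env(x))|``
    where ``a|b`` is ``a`` orthogonalized with respect to ``b``.  Zero-lag
    (volume-conduction-like) coupling is removed by construction; a pair
    that couples *only* at zero lag leaves a degenerate residual and
    raises rather than returning a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scale = max(float(np.std(x)), float(np.std(y)), np.finfo(float).tiny)
    vals = []
    for a, b in ((x, y), (y, x)):
        r = orthogonalize(a, b)
        if float(np.std(r)) < 1e-9 * scale:
            raise DegenerateInputError(
                "aec_c: residual after orthogonalization is degenerate (colinear inputs)"
            )
        env_r = _envelope(r, edge_trim)
        env_b = _envelope(b, edge_trim)
        if log_env:
            env_r, env_b = np.log(env_r + 1e-12), np.log(env_b + 1e-12)
        c = aec(env_r, env_b)
        vals.append(abs(c) if use_abs else c)
    return float(np.mean(vals))


def aecc_matrix(
    ep: EpochedRecording,
    edge_trim: float = EDGE_TRIM_FRACTION,
    use_abs: bool = True,
    log_env: bool = False,
) -> ConnectivityMatrix:
    """Per-subject AEC-c matrix: per pair per epoch, averaged across epochs.

    Vectorized: residuals for all ordered channel pairs of one epoch are
    Hilbert-transformed in one batched FFT.  A degenerate pair (constant
    envelope or colinear channels) raises ``DegenerateInputError`` naming
    the pair; degeneracy never silently becomes a zero entry.
    """
    if ep.n_epochs < 1:
        raise DataError(f"subject {ep.subject_id!r}: no epochs")
    n_ep, n_ch, _ = ep.epochs.shape
    acc = np.zeros((n_ch, n_ch))
    eps_std = 1e-9
    for e in range(n_ep):
        X = ep.epochs[e]  # (n_ch, n_s)
        Xc = X - X.mean(axis=1, keepdims=True)
        var = np.einsum("is,is->i", Xc, Xc)
        if np.any(var <= np.finfo(float).tiny * X.shape[1]):
            bad = ep.channel_labels[int(np.argmin(var))]
            raise DegenerateInputError(
                f"subject {ep.subject_id!r}: channel {bad} is constant in epoch {e}"
            )
        # beta[i, j]: coefficient of channel j in the regression of i on j
        beta = (Xc @ Xc.T) / var[None, :]
        # residual R[i, j, :] = X[i] - beta[i, j] * X[j]
        R = X[:, None, :] - beta[:, :, None] * X[None, :, :]
        rstd = R.std(axis=-1)
        scale = np.sqrt(var / X.shape[1])
        pair_scale = np.maximum(scale[:, None], scale[None, :])
        off = ~np.eye(n_ch, dtype=bool)
        if np.any((rstd < eps_std * pair_scale) & off):
            i, j = np.argwhere((rstd < eps_std * pair_scale) & off)[0]
            raise DegenerateInputError(
                f"subject {ep.subject_id!r}: channels {ep.channel_labels[i]}/"
                f"{ep.channel_labels[j]} colinear in epoch {e}"
            )
        env_R = trim_edges(np.abs(hilbert(R, axis=-1)), edge_trim, axis=-1)
        env_X = trim_edges(np.abs(hilbert(X, axis=-1)), edge_trim, axis=-1)
        if log_env:
            env_R = np.log(env_R + 1e-12)
            env_X = np.log(env_X + 1e-12)
        # corr(env_R[i, j], env_X[j]) for every ordered pair
        eRc = env_R - env_R.mean(axis=-1, keepdims=True)
        eXc = env_X - env_X.mean(axis=-1, keepdims=True)
        num = np.einsum("ijs,js->ij", eRc, eXc)
        den = np.sqrt(np.einsum("ijs,ijs->ij", eRc, eRc) * np.einsum("js,js->j", eXc, eXc)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = num / den
        if use_abs:
            corr = np.abs(corr)
        pairvals = 0.5 * (corr + corr.T)
        np.fill_diagonal(pairvals, 0.0)
        if not np.all(np.isfinite(pairvals)):
            i, j = np.argwhere(~np.isfinite(pairvals))[0]
            raise DegenerateInputError(
                f"subject {ep.subject_id!r}: undefined envelope correlation for "
                f"{ep.channel_labels[i]}/{ep.channel_labels[j]} in epoch {e}"
            )
        acc += pairvals
    values = acc / n_ep
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)
    return ConnectivityMatrix(
        values=values,
        metric="AEC_c",
        band=ep.band,
        channel_labels=ep.channel_labels,
        subject_id=ep.subject_id,
        group=ep.group,
        n_epochs_averaged=n_ep,
    )


def mean_connectivity(m: ConnectivityMatrix) -> float:
    """Mean coupling over the strict upper triangle (diagonal excluded)."""
    iu = np.triu_indices(m.n_channels, k=1)
    return float(m.values[iu].mean())


def group_average(ms: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entrywise mean of per-subject matrices sharing band, metric, montage."""
    if not ms:
        raise DataError("group_average: empty list")
    first = ms[0]
    for m in ms[1:]:
        if m.metric != first.metric:
            raise DataError(f"mixed metrics: {m.metric} vs {first.metric}")
        if m.band.name != first.band.name:
            raise DataError(f"mixed bands: {m.band.name} vs {first.band.name}")
        if tuple(c.lower() for c in m.channel_labels) != tuple(
            c.lower() for c in first.channel_labels
        ):
            raise DataError("mixed channel montages")
    values = np.mean([m.values for m in ms], axis=0)
    groups = {m.group for m in ms}
    return ConnectivityMatrix(
        values=values,
        metric=first.metric,
        band=first.band,
        channel_labels=first.channel_labels,
        subject_id=f"mean_of_{len(ms)}",
        group=groups.pop() if len(groups) == 1 else "mixed",
        n_epochs_averaged=len(ms),
    )
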
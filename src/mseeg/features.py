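"""Per-segment EEG descriptors and feature-matrix assembly.

Four descriptor families are computed for every segment (one frame of
one band of one channel):

* **statistical** (time domain): rectified integral, mean absolute
  value, absolute raw moments of order 3-5 of the mean-removed segment,
  RMS, v-order statistic (v = 3), waveform length, zero crossings;
* **entropy**: sample entropy (template irregularity, time domain) and
  spectral entropy (Shannon entropy of the normalized Welch spectrum,
  frequency domain);
* **fractal** (time domain): Katz, Higuchi, Petrosian and
  Grassberger-Procaccia correlation dimensions;
* **spectral** (frequency domain): total Welch power and peak frequency.

Sample entropy follows the standard convention: template length m = 2,
tolerance r = 0.2 x SD, Chebyshev distance, self-matches excluded,
SampEn = -ln(A/B) with A and B the (m+1)- and m-template match counts.

The Katz dimension uses the amplitude-difference form
``D = log(N-1) / (log(N-1) + log(d/Len))`` with ``Len`` the summed
absolute successive differences and ``d`` the maximal excursion from the
first sample — the form in common use, which is exactly 1 on a ramp and
rises sharply on irregular signals.

Rows of the assembled matrix are (recording, frame) pairs — or one row
per recording when frame aggregation is on — and columns are named
``band.channel.feature`` with a group tag and a time/frequency domain
tag per column.  Z-scoring is fitted on caller-designated training rows
only and stored with the matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.spatial.distance import pdist

from .preprocess import BAND_ORDER, Segment

__all__ = [
    "FeatureError",
    "PSDEstimate",
    "FeatureConfig",
    "FeatureMatrix",
    "welch_psd",
    "sample_entropy",
    "spectral_entropy",
    "katz_fd",
    "higuchi_fd",
    "petrosian_fd",
    "correlation_dimension",
    "statistical_features",
    "compute_segment_features",
    "build_feature_matrix",
    "FEATURE_GROUPS",
    "FEATURE_DOMAINS",
]

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """Invalid input to a feature computation."""


# ---------------------------------------------------------------------------
# Spectral estimation
# ---------------------------------------------------------------------------


@dataclass
class PSDEstimate:
    """One-sided Welch power spectral density.

    ``power`` is the mean of ``L`` modified periodograms of overlapping
    windowed segments (density scaling, so the integral over frequency
    approximates the signal variance).
    """

    frequencies: np.ndarray
    power: np.ndarray
    L: int
    window_name: str
    welch_overlap: float

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.frequencies))

    @property
    def peak_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.power))])


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len: int = 128,
    welch_overlap: float = 0.5,
    window: str = "hamming",
) -> PSDEstimate:
    """Averaged-periodogram PSD estimate.

    Raises
    ------
    FeatureError
        If ``seg_len`` exceeds the signal length.
    """
    x = np.asarray(x, dtype=float).ravel()
    if seg_len > x.size:
        raise FeatureError(f"seg_len {seg_len} exceeds signal length {x.size}")
    noverlap = int(seg_len * welch_overlap)
    freqs, power = sps.welch(
        x, fs=fs, window=window, nperseg=seg_len, noverlap=noverlap, detrend=False
    )
    step = seg_len - noverlap
    L = (x.size - seg_len) // step + 1
    return PSDEstimate(
        frequencies=freqs,
        power=power,
        L=L,
        window_name=window,
        welch_overlap=welch_overlap,
    )


def spectral_entropy(psd, normalize: bool = False) -> float:
    """Shannon entropy of the normalized spectral distribution.

    ``psd`` may be a :class:`PSDEstimate` or a raw nonnegative power
    array.  With ``normalize`` the value is divided by ``ln N`` to lie
    in [0, 1].  The ``0 * ln 0`` terms are taken as 0.

    Raises
    ------
    FeatureError
        If fewer than two bins or all-zero power.
    """
    power = psd.power if isinstance(psd, PSDEstimate) else np.asarray(psd, dtype=float)
    power = power.ravel()
    if power.size < 2:
        raise FeatureError("spectral entropy needs at least two bins")
    if np.any(power < 0):
        raise FeatureError("power spectrum must be nonnegative")
    total = power.sum()
    if total <= 0:
        raise FeatureError("spectral entropy undefined for an all-zero spectrum")
    p = power / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    if normalize:
        h /= np.log(power.size)
    return h


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) of a series.

    Counts pairs of length-``m`` templates within Chebyshev distance
    ``r`` (B) and pairs of length-``m+1`` templates within ``r`` (A),
    excluding self-matches, and returns ``-ln(A/B)``.  A constant series
    gives 0 (every template matches at both lengths); if no ``m+1``
    template pairs match, ``inf`` is returned as a sentinel.

    Parameters
    ----------
    r : float, optional
        Match tolerance; defaults to ``0.2 * std(x)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise FeatureError(f"tolerance r must be positive, got {r}")
    if x.size <= m + 1:
        raise FeatureError(f"series of length {x.size} too short for m={m}")

    # Chebyshev template distance as a running max over diagonal shifts of
    # the pointwise |x_i - x_j| matrix; both template lengths use the same
    # N - m start positions.
    pointwise = np.abs(x[:, None] - x[None, :])
    n_t = x.size - m

    def _count(length: int) -> int:
        d = pointwise[:n_t, :n_t].copy()
        for t in range(1, length):
            np.maximum(d, pointwise[t : t + n_t, t : t + n_t], out=d)
        within = int((d <= r).sum())
        return (within - n_t) // 2  # drop self-matches, halve symmetric pairs

    b = _count(m)
    a = _count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# Fractal dimensions
# ---------------------------------------------------------------------------


def _slope(lx: np.ndarray, ly: np.ndarray) -> float:
    """Least-squares slope of ly against lx."""
    lx = lx - lx.mean()
    return float((lx @ (ly - ly.mean())) / (lx @ lx))


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of a waveform.

    ``D = log(N') / (log(N') + log(d / Len))`` with ``N' = N - 1``,
    ``Len`` the total curve length (sum of absolute successive
    differences) and ``d`` the maximum excursion from the first sample.
    Exactly 1 for a monotone ramp.

    Raises
    ------
    FeatureError
        For constant series (zero curve length) or length < 3.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise FeatureError("Katz dimension needs at least 3 samples")
    dists = np.abs(np.diff(x))
    length = dists.sum()
    if length == 0:
        raise FeatureError("Katz dimension undefined for a constant series")
    d = np.abs(x - x[0]).max()
    n = x.size - 1
    return float(np.log(n) / (np.log(n) + np.log(d / length)))


def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension.

    For each delay ``k`` and offset ``m`` the normalized curve length of
    the subsampled series ``x[m], x[m+k], x[m+2k], ...`` is

    ``L_m(k) = [ sum |x[m+ik] - x[m+(i-1)k]| * (N-1) / (n_k * k) ] / k``

    with ``n_k`` the number of increments; ``L(k)`` averages over the
    ``k`` offsets and the dimension is the slope of ``ln L(k)`` against
    ``ln(1/k)``.  About 1 for smooth curves, about 2 for white noise.
    """
    x = np.asarray(x, dtype=float).ravel()
    if k_max < 2:
        raise FeatureError(f"k_max must be >= 2, got {k_max}")
    n = x.size
    if n < 2 * k_max:
        raise FeatureError(f"series of length {n} too short for k_max={k_max}")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            nk = idx.size - 1
            lm = np.abs(np.diff(x[idx])).sum() * (n - 1) / (nk * k) / k
            lengths.append(lm)
        lk[k - 1] = np.mean(lengths)
    ks = np.arange(1, k_max + 1)
    good = lk > 0
    if good.sum() < 2:
        raise FeatureError("degenerate series: curve lengths vanish")
    return _slope(np.log(1.0 / ks[good]), np.log(lk[good]))


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the first difference.

    ``D = log10(N) / (log10(N) + log10(N / (N + 0.4 * N_delta)))`` where
    ``N_delta`` counts strict sign alternations of successive
    differences; monotone series give exactly 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise FeatureError("Petrosian dimension needs at least 3 samples")
    d = np.diff(x)
    n_delta = int(np.sum(d[:-1] * d[1:] < 0))
    n = x.size
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def correlation_dimension(
    x: np.ndarray,
    embed_dim: int = 2,
    delay: int = 1,
    radii: np.ndarray | None = None,
    n_radii: int = 20,
) -> float:
    """Grassberger-Procaccia correlation dimension.

    The series is delay-embedded into ``embed_dim`` dimensions, the
    correlation sum ``C(rho)`` (fraction of point pairs within distance
    ``rho``) is evaluated on a log-spaced radius grid, and the dimension
    is the least-squares slope of ``log C`` against ``log rho`` over the
    central quartiles of the grid.  The default grid runs from the 2nd
    percentile to the *median* of the pairwise distances: beyond the
    median the correlation sum saturates toward 1 and its local slope no
    longer reflects the attractor dimension.

    Raises
    ------
    FeatureError
        If fewer than 10 embedded points remain.
    """
    x = np.asarray(x, dtype=float).ravel()
    if embed_dim < 2:
        raise FeatureError("embed_dim must be >= 2")
    n_points = x.size - (embed_dim - 1) * delay
    if n_points < 10:
        raise FeatureError("too few embedded points for a correlation sum")
    emb = np.stack([x[i * delay : i * delay + n_points] for i in range(embed_dim)], axis=1)
    d = np.sort(pdist(emb))
    if d[-1] == 0:
        raise FeatureError("degenerate embedding: all points coincide")
    if radii is None:
        positive = d[d > 0]
        dmin = max(np.percentile(positive, 2.0), d[-1] * 1e-6)
        dmid = np.percentile(positive, 50.0)
        if dmid <= dmin:  # near-degenerate distance distribution
            dmid = d[-1]
        radii = np.logspace(np.log10(dmin), np.log10(dmid), n_radii)
    radii = np.asarray(radii, dtype=float)
    c = np.searchsorted(d, radii, side="right") / d.size
    lo, hi = len(radii) // 4, 3 * len(radii) // 4 + 1
    rr, cc = radii[lo:hi], c[lo:hi]
    keep = cc > 0
    if keep.sum() < 2:
        raise FeatureError("correlation sum empty over the scaling region")
    return _slope(np.log(rr[keep]), np.log(cc[keep]))


# ---------------------------------------------------------------------------
# Time-domain statistics
# ---------------------------------------------------------------------------


def statistical_features(x: np.ndarray, v: int = 3) -> dict[str, float]:
    """The time-domain statistical descriptor set of one segment.

    Moments of order 3-5 are absolute raw moments of the mean-removed
    segment (band signals are near zero-mean already, so this is a mild
    detrend rather than a re-centering).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise FeatureError("statistical features need at least 2 samples")
    ax = np.abs(x)
    xc = x - x.mean()
    return {
        "integral": float(ax.sum()),
        "mav": float(ax.mean()),
        "moment3": float(abs(np.mean(xc**3))),
        "moment4": float(abs(np.mean(xc**4))),
        "moment5": float(abs(np.mean(xc**5))),
        "rms": float(np.sqrt(np.mean(x**2))),
        "v_order": float(np.mean(ax**v) ** (1.0 / v)),
        "waveform_length": float(np.abs(np.diff(x)).sum()),
        "zero_crossings": float(np.sum(x[:-1] * x[1:] < 0)),
    }


# ---------------------------------------------------------------------------
# Catalog and matrix assembly
# ---------------------------------------------------------------------------

_STATISTICAL = (
    "integral",
    "mav",
    "moment3",
    "moment4",
    "moment5",
    "rms",
    "v_order",
    "waveform_length",
    "zero_crossings",
)

#: Feature name -> descriptor group.
FEATURE_GROUPS: dict[str, str] = {
    **{name: "statistical" for name in _STATISTICAL},
    "sample_entropy": "entropy",
    "spectral_entropy": "entropy",
    "katz_fd": "fractal",
    "higuchi_fd": "fractal",
    "petrosian_fd": "fractal",
    "correlation_dim": "fractal",
    "total_power": "spectral",
    "peak_freq": "spectral",
}

#: Feature name -> analysis domain (the model-1/model-2 split).
FEATURE_DOMAINS: dict[str, str] = {
    **{name: "time" for name in _STATISTICAL},
    "sample_entropy": "time",
    "spectral_entropy": "frequency",
    "katz_fd": "time",
    "higuchi_fd": "time",
    "petrosian_fd": "time",
    "correlation_dim": "time",
    "total_power": "frequency",
    "peak_freq": "frequency",
}


@dataclass
class FeatureConfig:
    """Which descriptors to compute and with what parameters."""

    groups: tuple[str, ...] = ("statistical", "entropy", "fractal", "spectral")
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    welch_seg_len: int = 128
    welch_overlap: float = 0.5
    welch_window: str = "hamming"
    spectral_entropy_normalize: bool = False
    higuchi_k_max: int = 8
    corr_embed_dim: int = 2
    corr_delay: int = 1
    v_order: int = 3
    #: "none" keeps one row per (recording, frame); "recording" averages
    #: every recording's frames into a single row.
    aggregate: str = "recording"
    #: Average homologous columns across channels (column tag "avg").
    channel_average: bool = True

    def enabled_features(self) -> list[str]:
        return [f for f, g in FEATURE_GROUPS.items() if g in self.groups]


def compute_segment_features(
    x: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> dict[str, float]:
    """All enabled descriptors of one segment, name -> value."""
    config = config or FeatureConfig()
    x = np.asarray(x, dtype=float).ravel()
    out: dict[str, float] = {}
    if "statistical" in config.groups:
        out.update(statistical_features(x, v=config.v_order))

    psd: PSDEstimate | None = None
    if "entropy" in config.groups or "spectral" in config.groups:
        psd = welch_psd(
            x,
            fs,
            seg_len=min(config.welch_seg_len, x.size),
            welch_overlap=config.welch_overlap,
            window=config.welch_window,
        )
    if "entropy" in config.groups:
        sd = x.std()
        out["sample_entropy"] = (
            sample_entropy(x, m=config.sampen_m, r=config.sampen_r_factor * sd)
            if sd > 0
            else 0.0
        )
        out["spectral_entropy"] = spectral_entropy(
            psd, normalize=config.spectral_entropy_normalize
        )
    if "fractal" in config.groups:
        out["katz_fd"] = katz_fd(x)
        out["higuchi_fd"] = higuchi_fd(x, k_max=config.higuchi_k_max)
        out["petrosian_fd"] = petrosian_fd(x)
        out["correlation_dim"] = correlation_dimension(
            x, embed_dim=config.corr_embed_dim, delay=config.corr_delay
        )
    if "spectral" in config.groups:
        out["total_power"] = psd.total_power
        out["peak_freq"] = psd.peak_frequency
    return out


def _min_segment_length(config: FeatureConfig) -> int:
    n = 3
    if "fractal" in config.groups:
        n = max(n, 2 * config.higuchi_k_max, 10 + (config.corr_embed_dim - 1) * config.corr_delay)
    if "entropy" in config.groups:
        n = max(n, config.sampen_m + 2)
    return n


@dataclass
class FeatureMatrix:
    """Named feature columns with group/domain tags and z-score state.

    ``values`` holds raw (unstandardized) features; ``transform``
    applies the z-scoring fitted by :meth:`fit_standardize` (training
    rows only, to keep test folds untouched).
    """

    values: pd.DataFrame
    groups: dict[str, str]
    domains: dict[str, str]
    standardization: dict[str, tuple[float, float]] | None = None
    labels: pd.Series | None = None
    recording_ids: pd.Series | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def columns_in_groups(self, groups: set[str] | tuple[str, ...]) -> list[str]:
        return [c for c in self.columns if self.groups[c] in groups]

    def columns_in_domains(self, domains: set[str] | tuple[str, ...]) -> list[str]:
        return [c for c in self.columns if self.domains[c] in domains]

    def fit_standardize(self, rows: np.ndarray | list[int]) -> None:
        """Fit per-column mean/SD on the given (training) row positions."""
        sub = self.values.iloc[list(rows)]
        params = {}
        for c in self.columns:
            mu = float(sub[c].mean())
            sd = float(sub[c].std(ddof=0))
            params[c] = (mu, sd if sd > 0 else 1.0)
        self.standardization = params

    def transform(self, rows: np.ndarray | list[int] | None = None) -> pd.DataFrame:
        """Standardized view of all rows (or the given row positions)."""
        if self.standardization is None:
            raise FeatureError("standardization has not been fitted")
        df = self.values if rows is None else self.values.iloc[list(rows)]
        mu = pd.Series({c: p[0] for c, p in self.standardization.items()})
        sd = pd.Series({c: p[1] for c, p in self.standardization.items()})
        return (df - mu) / sd


def build_feature_matrix(
    segments: list[Segment], config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Assemble the feature matrix from a list of segments.

    Rows are keyed by (recording, frame); each segment contributes its
    features under columns ``band.ch<k>.<feature>``.  Segments shorter
    than the minimum any enabled descriptor requires are skipped with a
    warning.  With ``config.channel_average`` homologous columns are
    averaged across channels (tag ``avg``); with ``config.aggregate ==
    "recording"`` each recording's frame rows are averaged into one.
    """
    config = config or FeatureConfig()
    if not segments:
        raise FeatureError("no segments given")
    fs = segments[0].fs
    min_len = _min_segment_length(config)

    rows: dict[tuple[str, int], dict[str, float]] = {}
    row_labels: dict[tuple[str, int], str] = {}
    for seg in segments:
        if seg.fs != fs:
            raise FeatureError("segments do not share a sampling rate")
        if seg.samples.size < min_len:
            warnings.warn(
                f"segment {seg.recording_id}/{seg.band}/ch{seg.channel}/f{seg.frame_index} "
                f"of length {seg.samples.size} below minimum {min_len}; skipped",
                stacklevel=2,
            )
            continue
        key = (seg.recording_id, seg.frame_index)
        feats = compute_segment_features(seg.samples, fs, config)
        row = rows.setdefault(key, {})
        for name, value in feats.items():
            row[f"{seg.band}.ch{seg.channel}.{name}"] = value
        row_labels[key] = seg.label

    if not rows:
        raise FeatureError("all segments were skipped")
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index = pd.MultiIndex.from_tuples(df.index, names=["recording_id", "frame"])
    labels = pd.Series({k: row_labels[k] for k in df.index.to_list()})
    labels.index = df.index

    if config.channel_average:
        grouped: dict[str, list[str]] = {}
        for col in df.columns:
            band, _ch, feat = col.split(".", 2)
            grouped.setdefault(f"{band}.avg.{feat}", []).append(col)
        df = pd.DataFrame(
            {new: df[cols].mean(axis=1) for new, cols in grouped.items()}, index=df.index
        )

    if config.aggregate == "recording":
        df = df.groupby(level="recording_id").mean()
        labels = labels.groupby(level="recording_id").first()
        rec_ids = pd.Series(df.index, index=df.index)
    elif config.aggregate == "none":
        rec_ids = pd.Series(df.index.get_level_values("recording_id"), index=df.index)
    else:
        raise FeatureError(f"unknown aggregate mode {config.aggregate!r}")

    if df.isna().any().any():
        raise FeatureError("feature matrix contains missing values")

    groups = {c: FEATURE_GROUPS[c.rsplit(".", 1)[1]] for c in df.columns}
    domains = {c: FEATURE_DOMAINS[c.rsplit(".", 1)[1]] for c in df.columns}
    return FeatureMatrix(
        values=df, groups=groups, domains=domains, labels=labels, recording_ids=rec_ids
    )
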
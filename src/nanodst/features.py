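"""Scalar features derived from quantile spectrograms.

Each feature is a named, fully parameterized descriptor: a statistic
(band power, spikiness, Jensen-Shannon distance to a chi-squared reference,
or a ratio/difference between quantile levels) evaluated per time window on
one frequency band of the quantile spectrogram at one quantile level,
summarized by a percentile over the windows of a stated time interval, and
optionally combined (difference or ratio) between two intervals.

Conventions are half-open everywhere: bands are [f_lo, f_hi) Hz, intervals
are [t_lo, t_hi) minutes on the recording clock, and windows belong to an
interval when their *start* lies in it.  Every feature value is reproducible
from the spectrogram plus the descriptor's canonical name alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import chi2 as chi2_dist

from .quantile_spectra import QuantileSpectrogram

KINDS = ("band_power", "spikiness", "js_chi2", "quantile_ratio", "quantile_difference")
_PAIR_KINDS = ("quantile_ratio", "quantile_difference")


class FeatureError(ValueError):
    """A descriptor does not apply to the given spectrogram axes."""


def spikiness(band_powers: np.ndarray) -> float:
    """Peakedness of a band: max over median of its PSD values (>= 1, scale-free).

    Raises on non-positive values — PSD ordinates are expected positive.
    """
    v = np.asarray(band_powers, dtype=float)
    if v.size < 2:
        raise ValueError("spikiness needs at least 2 values")
    if np.any(v <= 0):
        raise ValueError("spikiness requires strictly positive band powers")
    return float(np.max(v) / np.median(v))


def js_chi2(band_powers: np.ndarray, df: float = 2.0, n_bins: int = 16) -> float:
    """Jensen-Shannon distance between band powers and a chi-squared reference.

    The chi-squared(df) reference is scaled to the empirical mean, the
    positive axis is partitioned into ``n_bins`` equal-probability bins of
    the scaled reference, and the base-2 Jensen-Shannon distance (square
    root of the divergence; a metric in [0, 1]) between the empirical bin
    frequencies and the uniform reference mass is returned.

    df = 2 corresponds to the law of raw periodogram ordinates of Gaussian
    noise (exponential); the quantile-spectrum values fed here are order
    statistics of that law, so df stays configurable.
    """
    v = np.asarray(band_powers, dtype=float)
    if v.size < n_bins:
        raise ValueError(f"js_chi2 needs at least {n_bins} values, got {v.size}")
    if np.any(v <= 0):
        raise ValueError("js_chi2 requires strictly positive band powers")
    scale = v.mean() / df  # chi-squared(df) has mean df
    edges = scale * chi2_dist.ppf(np.arange(1, n_bins) / n_bins, df)
    counts = np.bincount(np.searchsorted(edges, v), minlength=n_bins)
    empirical = counts / v.size
    reference = np.full(n_bins, 1.0 / n_bins)
    return float(jensenshannon(empirical, reference, base=2))


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class FeatureDescriptor:
    kind: str
    band_hz: tuple[float, float]
    level: float | tuple[float, float]
    interval_min: tuple[float, float]
    summary_pct: float
    combinator: str = "value"
    interval2_min: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band must have f_lo < f_hi")
        if not self.interval_min[0] < self.interval_min[1]:
            raise ValueError("interval must have t_lo < t_hi")
        if not 0 < self.summary_pct < 100:
            raise ValueError("summary percentile must lie in (0, 100)")
        if self.combinator not in ("value", "difference", "ratio"):
            raise ValueError(f"unknown combinator {self.combinator!r}")
        if self.combinator != "value" and self.interval2_min is None:
            raise ValueError(f"combinator {self.combinator!r} needs a second interval")
        pair = isinstance(self.level, tuple)
        if pair != (self.kind in _PAIR_KINDS):
            raise ValueError(
                f"kind {self.kind!r} needs a "
                f"{'pair of levels' if self.kind in _PAIR_KINDS else 'single level'}"
            )

    @property
    def name(self) -> str:
        """Canonical, unique, order-stable serialization of the descriptor."""
        if isinstance(self.level, tuple):
            lvl = f"q{_fmt(self.level[0])}/{_fmt(self.level[1])}"
        else:
            lvl = f"q{_fmt(self.level)}"
        s = (
            f"{self.kind}[{_fmt(self.band_hz[0])}-{_fmt(self.band_hz[1])}Hz]"
            f"{lvl}t[{_fmt(self.interval_min[0])}-{_fmt(self.interval_min[1])}min]"
            f"p{_fmt(self.summary_pct)}"
        )
        if self.combinator != "value":
            s += (
                f"{self.combinator}t2[{_fmt(self.interval2_min[0])}-"
                f"{_fmt(self.interval2_min[1])}min]"
            )
        return s


_NAME_RE = re.compile(
    r"^(?P<kind>[a-z0-9_]+)"
    r"\[(?P<flo>[0-9.eE+]+)-(?P<fhi>[0-9.eE+]+)Hz\]"
    r"q(?P<level>[0-9.]+(?:/[0-9.]+)?)"
    r"t\[(?P<t0>[0-9.]+)-(?P<t1>[0-9.]+)min\]"
    r"p(?P<pct>[0-9.]+)"
    r"(?:(?P<comb>difference|ratio)t2\[(?P<s0>[0-9.]+)-(?P<s1>[0-9.]+)min\])?$"
)


def parse_descriptor(name: str) -> FeatureDescriptor:
    """Invert :attr:`FeatureDescriptor.name`; feature provenance is total."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable descriptor name {name!r}")
    level: float | tuple[float, float]
    if "/" in m["level"]:
        a, b = m["level"].split("/")
        level = (float(a), float(b))
    else:
        level = float(m["level"])
    return FeatureDescriptor(
        kind=m["kind"],
        band_hz=(float(m["flo"]), float(m["fhi"])),
        level=level,
        interval_min=(float(m["t0"]), float(m["t1"])),
        summary_pct=float(m["pct"]),
        combinator=m["comb"] or "value",
        interval2_min=(float(m["s0"]), float(m["s1"])) if m["comb"] else None,
    )


def _level_index(spec: QuantileSpectrogram, level: float) -> int:
    idx = np.nonzero(np.isclose(spec.levels, level))[0]
    if idx.size == 0:
        raise FeatureError(f"quantile level {level} not in spectrogram levels")
    return int(idx[0])


def band_values(
    spec: QuantileSpectrogram,
    band_hz: tuple[float, float],
    level: float,
    interval_min: tuple[float, float],
) -> list[np.ndarray]:
    """Per-window vectors of spectrogram values for one band/level/interval.

    One vector per window whose start lies in [t_lo, t_hi), holding the
    values at the given quantile level over bins with f_lo <= f < f_hi.
    """
    li = _level_index(spec, level)
    fmask = (spec.freqs_hz >= band_hz[0]) & (spec.freqs_hz < band_hz[1])
    if not fmask.any():
        raise FeatureError(
            f"band [{band_hz[0]}, {band_hz[1]}) Hz contains no frequency bins"
        )
    wmask = (spec.window_starts_min >= interval_min[0]) & (
        spec.window_starts_min < interval_min[1]
    )
    if not wmask.any():
        raise FeatureError(
            f"interval [{interval_min[0]}, {interval_min[1]}) min contains no windows"
        )
    block = spec.values[li][np.ix_(fmask, wmask)]
    return [block[:, j] for j in range(block.shape[1])]


def _window_values(desc: FeatureDescriptor, spec: QuantileSpectrogram, interval) -> np.ndarray:
    """One descriptor value per window of the interval."""
    if desc.kind in _PAIR_KINDS:
        num = band_values(spec, desc.band_hz, desc.level[0], interval)
        den = band_values(spec, desc.band_hz, desc.level[1], interval)
        a = np.array([v.mean() for v in num])
        b = np.array([v.mean() for v in den])
        return a / b if desc.kind == "quantile_ratio" else a - b
    vals = band_values(spec, desc.band_hz, desc.level, interval)
    if desc.kind == "band_power":
        return np.array([v.mean() for v in vals])
    if desc.kind == "spikiness":
        return np.array([spikiness(v) for v in vals])
    return np.array([js_chi2(v) for v in vals])  # js_chi2


def summarize(desc: FeatureDescriptor, spec: QuantileSpectrogram) -> float:
    """Evaluate a descriptor on a spectrogram: pool per-window values over
    the interval, take the summary percentile, then apply the combinator
    between the two intervals' summaries if one is configured."""
    pooled = _window_values(desc, spec, desc.interval_min)
    if pooled.size == 0:
        raise FeatureError(f"empty window pool for {desc.name}")
    first = float(np.percentile(pooled, desc.summary_pct))
    if desc.combinator == "value":
        return first
    pooled2 = _window_values(desc, spec, desc.interval2_min)
    second = float(np.percentile(pooled2, desc.summary_pct))
    return first - second if desc.combinator == "difference" else first / second


@dataclass(frozen=True)
class FeatureGrammar:
    """Cartesian grid of descriptors: {kinds} x {bands} x {levels} x
    {intervals} x {summary percentiles} x {combinators}.

    Cross-interval difference/ratio combinators are generated for every
    unordered pair of grammar intervals (first interval minus/over second, in
    grammar order).  The full grammar of the method reaches several hundred
    thousand columns at the finest grids; defaults here are desk-scale.
    """

    kinds: tuple[str, ...] = ("band_power", "spikiness")
    bands_hz: tuple[tuple[float, float], ...] = ((0.0, 10.0), (10.0, 100.0))
    levels: tuple[float, ...] = (0.1, 0.5, 0.9)
    level_pairs: tuple[tuple[float, float], ...] = ((0.9, 0.1),)
    intervals_min: tuple[tuple[float, float], ...] = ((120.0, 130.0), (210.0, 220.0))
    summary_pcts: tuple[float, ...] = (10.0, 50.0, 95.0)
    combinators: tuple[str, ...] = ("value",)


def generate_descriptors(grammar: FeatureGrammar) -> list[FeatureDescriptor]:
    """Enumerate the grammar deterministically, in canonical order."""
    out: list[FeatureDescriptor] = []
    for kind in grammar.kinds:
        levels = grammar.level_pairs if kind in _PAIR_KINDS else grammar.levels
        for band in grammar.bands_hz:
            for level in levels:
                for pct in grammar.summary_pcts:
                    for comb in grammar.combinators:
                        if comb == "value":
                            for interval in grammar.intervals_min:
                                out.append(
                                    FeatureDescriptor(kind, band, level, interval, pct)
                                )
                        else:
                            for i1, i2 in combinations(grammar.intervals_min, 2):
                                out.append(
                                    FeatureDescriptor(
                                        kind, band, level, i1, pct, comb, i2
                                    )
                                )
    return out


@dataclass
class FeatureMatrix:
    values: np.ndarray  # [n_samples, n_features]
    descriptors: list[FeatureDescriptor]
    sample_ids: list[str]
    labels: list[str]
    concentrations_uM: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.descriptors)):
            raise ValueError("feature matrix shape does not match ids/descriptors")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise FeatureError(
                f"non-finite feature values at (sample, feature) {bad[:5].tolist()}"
            )
        if not self.concentrations_uM:
            self.concentrations_uM = [0.0] * len(self.sample_ids)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "concentration_uM", self.concentrations_uM)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def build_feature_matrix(
    spectrograms: list[QuantileSpectrogram],
    grammar: FeatureGrammar | list[FeatureDescriptor],
    sample_ids: list[str] | None = None,
    labels: list[str] | None = None,
    concentrations_uM: list[float] | None = None,
) -> FeatureMatrix:
    """Assemble the cohort feature table; identical grammar + cohort gives an
    identical matrix.  Spectrograms must share level and frequency axes."""
    descriptors = (
        generate_descriptors(grammar) if isinstance(grammar, FeatureGrammar) else list(grammar)
    )
    if not spectrograms:
        raise ValueError("empty cohort")
    ref = spectrograms[0]
    mismatched = [
        i
        for i, s in enumerate(spectrograms)
        if not (
            np.array_equal(s.levels, ref.levels)
            and np.array_equal(s.freqs_hz, ref.freqs_hz)
        )
    ]
    if mismatched:
        raise FeatureError(f"spectrograms with mismatched axes at indices {mismatched}")
    values = np.array(
        [[summarize(d, s) for d in descriptors] for s in spectrograms]
    )
    n = len(spectrograms)
    return FeatureMatrix(
        values=values,
        descriptors=descriptors,
        sample_ids=sample_ids or [f"sample-{i}" for i in range(n)],
        labels=labels or ["unknown"] * n,
        concentrations_uM=concentrations_uM or [],
    )
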
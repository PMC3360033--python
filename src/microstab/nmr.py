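"""Reduction of 1D NMR spectra to normalized variable-width bucket tables.

Spectra are integrated over ~102 variable-width chemical-shift buckets
spanning 0.50-8.30 ppm, with the residual-water region 4.70-5.00 ppm
excluded, and each sample's integrals divided by their total so bucket
values are relative proton abundances. Bucket boundaries are placed by
valley-seeking adaptive binning: starting from an equal-width grid, each
boundary is snapped to the nearest local minimum of the cohort mean
spectrum, subject to minimum and maximum width constraints. Named
metabolites are quantified by summing normalized integrals over a
window of +/-0.05 ppm around the resonance center.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import NMRSpectrum

ANALYSIS_REGION = (0.50, 8.30)
WATER_EXCLUSION = (4.70, 5.00)

#: Quantification windows (resonance center +/- 0.05 ppm).
LACTATE_CH3_WINDOW = (1.28, 1.38)
LACTATE_CH_WINDOW = (4.06, 4.16)
ACETATE_WINDOW = (1.87, 1.97)
SUCCINATE_WINDOW = (2.36, 2.46)


def _subregions(region, exclude):
    """Analysis region minus exclusions, as ordered disjoint intervals."""
    pieces = [tuple(region)]
    for lo, hi in sorted(exclude):
        nxt = []
        for a, b in pieces:
            if hi <= a or lo >= b:
                nxt.append((a, b))
                continue
            if lo > a:
                nxt.append((a, lo))
            if hi < b:
                nxt.append((hi, b))
        pieces = nxt
    return pieces


class IntelligentBucketer(TransformerMixin, BaseEstimator):
    """Valley-seeking adaptive binning of 1D spectra.

    ``fit`` learns a common set of bucket boundaries from the cohort
    mean spectrum; ``transform`` integrates each spectrum over those
    buckets (trapezoidal rule) and normalizes every sample to total sum
    one. Buckets never cross the excluded water region.

    Attributes
    ----------
    boundaries_ : list of (low, high) ppm intervals, ordered, disjoint.
    """

    def __init__(self, region=ANALYSIS_REGION, exclude=(WATER_EXCLUSION,),
                 n_target: int = 102, min_width: float = 0.01,
                 max_width: float = 0.30, normalize: bool = True):
        self.region = region
        self.exclude = exclude
        self.n_target = n_target
        self.min_width = min_width
        self.max_width = max_width
        self.normalize = normalize

    def fit(self, X: Sequence[NMRSpectrum], y=None):
        spectra = list(X)
        if not spectra:
            raise ValueError("need at least one spectrum")
        ppm = spectra[0].ppm
        for s in spectra[1:]:
            if s.ppm.shape != ppm.shape or not np.allclose(s.ppm, ppm):
                raise ValueError("all spectra must share one ppm grid")
        if ppm[0] > self.region[0] + 1e-9 or ppm[-1] < self.region[1] - 1e-9:
            raise ValueError(
                f"grid [{ppm[0]:.3f}, {ppm[-1]:.3f}] does not cover region "
                f"{self.region}"
            )
        mean = np.mean([s.intensity for s in spectra], axis=0)
        pieces = _subregions(self.region, self.exclude)
        total_width = sum(b - a for a, b in pieces)
        boundaries: list[tuple[float, float]] = []
        remaining = self.n_target
        for k, (a, b) in enumerate(pieces):
            if k == len(pieces) - 1:
                n = max(1, remaining)
            else:
                n = max(1, round(self.n_target * (b - a) / total_width))
            remaining -= n
            boundaries.extend(self._bucket_piece(ppm, mean, a, b, n))
        # greedy valley splits of the widest buckets until the count is
        # back within n_target - 5 (snapping can merge boundaries away)
        while len(boundaries) < self.n_target - 5:
            widths = [hi - lo for lo, hi in boundaries]
            i = int(np.argmax(widths))
            lo, hi = boundaries[i]
            if widths[i] < 2 * self.min_width:
                break
            mask = (ppm >= lo + self.min_width) & (ppm <= hi - self.min_width)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                break
            cut = float(ppm[idx[np.argmin(mean[idx])]])
            boundaries[i: i + 1] = [(lo, cut), (cut, hi)]
        self.boundaries_ = boundaries
        return self

    def _bucket_piece(self, ppm, mean, lo, hi, n):
        edges = np.linspace(lo, hi, n + 1)
        spacing = (hi - lo) / n
        snapped = [lo]
        for e in edges[1:-1]:
            mask = (ppm >= e - spacing / 2) & (ppm <= e + spacing / 2)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                snapped.append(e)
                continue
            vals = mean[idx]
            vmin = vals.min()
            ties = idx[vals <= vmin + 1e-12 * (abs(vmin) + 1.0)]
            best = ties[np.argmin(np.abs(ppm[ties] - e))]
            snapped.append(float(ppm[best]))
        snapped.append(hi)
        # enforce monotonic, minimum-width edges
        edges_ok = [snapped[0]]
        for e in snapped[1:-1]:
            if e - edges_ok[-1] >= self.min_width and hi - e >= self.min_width:
                edges_ok.append(e)
        edges_ok.append(hi)
        # split any interval wider than max_width
        final = [edges_ok[0]]
        for e in edges_ok[1:]:
            while e - final[-1] > self.max_width + 1e-12:
                k = int(np.ceil((e - final[-1]) / self.max_width))
                final.append(final[-1] + (e - final[-1]) / k)
            final.append(e)
        return [(final[i], final[i + 1]) for i in range(len(final) - 1)]

    def transform(self, X: Sequence[NMRSpectrum]) -> pd.DataFrame:
        """Samples x buckets table of (normalized) integrals."""
        spectra = list(X)
        raw = np.array(
            [integrate_buckets(s, self.boundaries_) for s in spectra]
        )
        if self.normalize:
            raw = np.array([normalize_total_sum(r) for r in raw])
        cols = pd.IntervalIndex.from_tuples(self.boundaries_, closed="left")
        return pd.DataFrame(raw, index=[s.sample_id for s in spectra], columns=cols)


def intelligent_bucket(spectra: Sequence[NMRSpectrum], region=ANALYSIS_REGION,
                       exclude=(WATER_EXCLUSION,), n_target: int = 102,
                       min_width: float = 0.01,
                       max_width: float = 0.30) -> list[tuple[float, float]]:
    """Learn common bucket boundaries; see :class:`IntelligentBucketer`."""
    est = IntelligentBucketer(region=region, exclude=exclude, n_target=n_target,
                              min_width=min_width, max_width=max_width)
    return est.fit(spectra).boundaries_


def integrate_buckets(spectrum: NMRSpectrum,
                      boundaries: Iterable[tuple[float, float]]) -> np.ndarray:
    """Trapezoidal integral of the spectrum over each bucket interval.

    Interval endpoints falling between grid points are handled by linear
    interpolation, so adjacent buckets tile the region exactly.
    """
    ppm, inten = spectrum.ppm, spectrum.intensity
    out = []
    for lo, hi in boundaries:
        if lo < ppm[0] - 1e-9 or hi > ppm[-1] + 1e-9:
            raise ValueError(f"bucket ({lo}, {hi}) outside spectrum grid")
        inner = (ppm > lo) & (ppm < hi)
        xs = np.concatenate(([lo], ppm[inner], [hi]))
        ys = np.concatenate(
            ([np.interp(lo, ppm, inten)], inten[inner], [np.interp(hi, ppm, inten)])
        )
        out.append(float(np.trapezoid(ys, xs)))
    return np.array(out)


def normalize_total_sum(raw: np.ndarray) -> np.ndarray:
    """Divide integrals by their total so the profile sums to one."""
    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero integral vector")
    return raw / total


def quantify_metabolite(data: Union[pd.DataFrame, pd.Series, NMRSpectrum],
                        window: tuple[float, float]) -> Union[float, pd.Series]:
    """Relative abundance (percent) of signal inside a chemical-shift window.

    For a normalized bucket table (or one row of it): the sum of
    normalized integrals over buckets whose centers fall in the window,
    times 100. For a raw spectrum: the window integral over the total
    integral of the analysis region (water region excluded), times 100.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must have positive width")
    if isinstance(data, NMRSpectrum):
        num = integrate_buckets(data, [(lo, hi)])[0]
        den = integrate_buckets(data, _subregions(ANALYSIS_REGION,
                                                  [WATER_EXCLUSION])).sum()
        if den <= 0:
            raise ValueError("empty spectrum")
        return 100.0 * num / den
    if isinstance(data, pd.Series):
        table = data.to_frame().T
    else:
        table = data
    centers = np.array([(iv.left + iv.right) / 2 for iv in table.columns])
    mask = (centers >= lo) & (centers <= hi)
    vals = 100.0 * table.loc[:, mask].sum(axis=1)
    return float(vals.iloc[0]) if isinstance(data, pd.Series) else vals
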
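"""Library-size and expression normalizations.

Implements the median-of-ratios size-factor procedure, counts-per-million
scaling for coverage tracks, transcripts-per-million for expression tables,
and per-sample min-max rescaling for coverage comparison plots.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .quantify import CountMatrix, CoverageTrack


class NormalizationError(ValueError):
    pass


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample j, the factor is the median over features g of
    ``c_gj / geomean(c_g.)``, restricted to features with strictly positive
    counts in every sample (the geometric mean is computed in log space, so
    any zero disqualifies the feature).  The median is taken over the
    log-ratios, so an even number of qualifying features yields the
    geometric midpoint of the two central ratios — the convention of the
    standard size-factor estimator.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    values = counts.to_numpy(dtype=float)
    if values.size == 0:
        raise NormalizationError("size factors undefined: empty count matrix")
    mask = (values > 0).all(axis=1)
    if not mask.any():
        raise NormalizationError(
            "size factors undefined: no feature has all-positive counts"
        )
    logs = np.log(values[mask])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def cpm_track(
    track: CoverageTrack, s_j: float, mean_total_reads: float
) -> CoverageTrack:
    """Depth-normalize a binned coverage track to counts per million.

    Each bin value is divided by the sample's size factor and by the mean
    per-sample total read count of the analyzed set, then scaled by 1e6.
    """
    if s_j <= 0 or mean_total_reads <= 0:
        raise NormalizationError("size factor and mean read count must be positive")
    return replace(track, values=track.values / s_j / mean_total_reads * 1e6)


def tpm(
    counts: CountMatrix | pd.DataFrame, lengths: pd.Series | None = None
) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6.

    Samples with all-zero counts stay all-zero rather than dividing by
    zero.
    """
    if isinstance(counts, CountMatrix):
        lengths = counts.lengths
        counts = counts.counts
    if lengths is None:
        raise ValueError("feature lengths required")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise NormalizationError("all feature lengths must be positive")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    scale = totals.where(totals > 0, 1.0)  # keep all-zero samples at zero
    return rates.div(scale, axis=1) * 1e6


def minmax_rescale(track: CoverageTrack) -> CoverageTrack:
    """Rescale a track so its minimum is 0 and maximum 1.

    Constant tracks map to all zeros by convention (downstream I/O safety).
    """
    if track.values.size == 0:
        raise NormalizationError("cannot rescale an empty track")
    lo = track.values.min()
    hi = track.values.max()
    if hi == lo:
        return replace(track, values=np.zeros_like(track.values))
    return replace(track, values=(track.values - lo) / (hi - lo))
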
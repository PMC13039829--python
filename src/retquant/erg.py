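"""Electroretinogram (ERG) feature extraction and intensity-response tables.

The a-wave is the photoreceptor-driven negative deflection, measured from
baseline to the trough; the b-wave is the bipolar-cell-driven positive
deflection, measured from the a-wave trough to the subsequent peak.  Implicit
times are latencies from the flash to the respective extremum.  Degenerate
traces that lack a b-wave peak are handled with a reference implicit time
(typically the wild-type b-wave latency at the same flash intensity): the
b-amplitude is then read as the voltage at the reference time minus the
trough voltage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ErgTrace:
    """One recorded flash response."""

    time_ms: np.ndarray
    voltage_uV: np.ndarray
    flash_time_ms: float
    flash_intensity_log_photons_per_um2: float = np.nan
    adaptation: str = "dark"
    group: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uV = np.asarray(self.voltage_uV, dtype=float)
        if self.time_ms.shape != self.voltage_uV.shape:
            raise ValueError("time and voltage arrays differ in length")
        if self.time_ms.size < 2 or not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("time_ms must be strictly increasing")
        if not self.time_ms[0] <= self.flash_time_ms <= self.time_ms[-1]:
            raise ValueError("flash_time_ms outside the record")


@dataclass
class ErgFeatures:
    a_amplitude_uV: float
    a_implicit_ms: float
    b_amplitude_uV: float
    b_implicit_ms: float
    b_a_ratio: float
    mode: str  # "peak" | "reference"
    baseline_uV: float


def extract_erg_features(
    trace: ErgTrace,
    reference_implicit_ms: float | None = None,
    *,
    baseline_window_ms: float = 50.0,
    a_window_ms: float = 80.0,
) -> ErgFeatures:
    """Measure a-/b-wave amplitudes and implicit times from one trace.

    Baseline is the mean voltage over ``[flash - baseline_window_ms, flash)``.
    The a-trough is the minimum over ``(flash, flash + a_window_ms]``; the
    a-amplitude is baseline minus trough (floored at 0 for flat records).
    Without a reference, the b-peak is the maximum after the trough and the
    b-amplitude is peak minus trough.  With ``reference_implicit_ms`` the
    b-amplitude is the voltage at ``flash + reference`` minus the trough
    voltage, floored at 0, and ``mode`` is ``"reference"``.
    """
    t, v = trace.time_ms, trace.voltage_uV
    tf = trace.flash_time_ms

    pre = (t >= tf - baseline_window_ms) & (t < tf)
    if not pre.any():
        raise ValueError("no pre-flash baseline window in the record")
    baseline = float(v[pre].mean())

    win = (t > tf) & (t <= tf + a_window_ms)
    if not win.any():
        raise ValueError("no samples in the a-wave search window")
    idx_win = np.nonzero(win)[0]
    trough_idx = idx_win[np.argmin(v[idx_win])]
    # A record that only ever falls has no trough: reject strictly decreasing
    # post-flash records whose minimum sits on the final sample.
    post = v[t > tf]
    if trough_idx == t.size - 1 and np.all(np.diff(post) < 0):
        raise ValueError("no a-wave trough found: record is monotone decreasing")
    trough_v = float(v[trough_idx])
    a_amp = max(baseline - trough_v, 0.0)
    a_implicit = float(t[trough_idx] - tf)

    if reference_implicit_ms is not None:
        t_ref = tf + reference_implicit_ms
        if not t[0] <= t_ref <= t[-1]:
            raise ValueError("reference time outside the record")
        v_ref = float(np.interp(t_ref, t, v))
        b_amp = max(v_ref - trough_v, 0.0)
        b_implicit = float(reference_implicit_ms)
        mode = "reference"
    else:
        after = np.nonzero(t >= t[trough_idx])[0]
        peak_idx = after[np.argmax(v[after])]
        b_amp = max(float(v[peak_idx]) - trough_v, 0.0)
        b_implicit = float(t[peak_idx] - tf)
        mode = "peak"

    ratio = b_amp / a_amp if a_amp > 0 else np.nan
    return ErgFeatures(
        a_amplitude_uV=a_amp,
        a_implicit_ms=a_implicit,
        b_amplitude_uV=b_amp,
        b_implicit_ms=b_implicit,
        b_a_ratio=ratio,
        mode=mode,
        baseline_uV=baseline,
    )


def welch_ttest_p(x1: Sequence[float], x2: Sequence[float], *, equal_var: bool = False) -> float:
    """Two-sided unpaired t-test p-value (Welch by default)."""
    res = stats.ttest_ind(np.asarray(x1, float), np.asarray(x2, float),
                          equal_var=equal_var)
    return float(res.pvalue)


def intensity_response(
    traces: Iterable[ErgTrace],
    *,
    feature: str = "a_amplitude_uV",
    reference_by_intensity: dict[float, float] | None = None,
    reference_groups: frozenset[str] | set[str] = frozenset(),
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-intensity group summaries of one extracted feature.

    Features are extracted per trace (groups listed in ``reference_groups``
    use the reference-implicit-time rule via ``reference_by_intensity``), then
    aggregated to mean and SEM (sd/sqrt(n)) per (intensity, group).  When an
    intensity has exactly two groups with n >= 2 each, an unpaired two-sided
    t-test p-value is attached; otherwise the row is flagged untested.
    """
    rows = []
    for tr in traces:
        ref = None
        if tr.group in reference_groups and reference_by_intensity is not None:
            ref = reference_by_intensity.get(tr.flash_intensity_log_photons_per_um2)
        feats = extract_erg_features(tr, reference_implicit_ms=ref)
        rows.append(
            {
                "intensity": tr.flash_intensity_log_photons_per_um2,
                "group": tr.group,
                "value": getattr(feats, feature),
            }
        )
    df = pd.DataFrame(rows)
    summ = (
        df.groupby(["intensity", "group"])["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    summ["sem"] = summ["sd"] / np.sqrt(summ["n"])

    pvals = {}
    tested = {}
    for intensity, sub in df.groupby("intensity"):
        groups = sorted(sub["group"].unique())
        ok = len(groups) == 2 and all(
            (sub["group"] == g).sum() >= 2 for g in groups
        )
        tested[intensity] = ok
        if ok:
            x1 = sub.loc[sub["group"] == groups[0], "value"]
            x2 = sub.loc[sub["group"] == groups[1], "value"]
            pvals[intensity] = welch_ttest_p(x1, x2, equal_var=equal_var)
        else:
            pvals[intensity] = np.nan
    summ["p_value"] = summ["intensity"].map(pvals)
    summ["tested"] = summ["intensity"].map(tested)
    return summ.sort_values(["intensity", "group"]).reset_index(drop=True)
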
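"""Weather feature derivation and temperature-bin exposure construction.

From raw city-day meteorology (mean 2 m temperature, dew point, u/v wind
components, precipitation) this module derives the regression controls --
relative humidity via the Magnus-type saturation vapor pressure
E(T) = 6.11 * 10^(7.5 T / (237.7 + T)) in hPa, and scalar wind speed --
and the temperature-bin exposure dummies against the 12-18 deg C comfort
zone, including shifted (lag/lead) bin columns for the lagged-effects
analysis.

Units are fixed: temperatures in deg C, E(T) in hPa, wind in m/s;
precipitation is a pass-through control with no transformation. Bins are
lower-closed / upper-open, [lower, upper).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MAGNUS_T_MIN",
    "saturation_vapor_pressure",
    "relative_humidity",
    "wind_speed",
    "BinScheme",
    "assign_temp_bin",
    "add_weather_features",
    "add_exposure_lags",
    "binarize_covariate",
]

#: Lower domain bound of the Magnus-type formula (pole of the exponent).
MAGNUS_T_MIN = -237.7


def saturation_vapor_pressure(t):
    """Saturation vapor pressure E(T) = 6.11 * 10^(7.5 T / (237.7 + T)), hPa.

    ``t`` is air (or dew-point) temperature in deg C, scalar or array.
    The formula's domain requires t > -237.7 deg C.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= MAGNUS_T_MIN):
        raise ValueError(f"temperature must exceed {MAGNUS_T_MIN} deg C")
    e = 6.11 * 10.0 ** (7.5 * t / (237.7 + t))
    return float(e) if e.ndim == 0 else e


def relative_humidity(t_mean, t_dew):
    """Relative humidity in %: 100 * E(t_dew) / E(t_mean).

    Exceeds 100 only when the dew point exceeds the air temperature
    (supersaturation in the inputs is passed through, not clipped).
    """
    return 100.0 * saturation_vapor_pressure(t_dew) / saturation_vapor_pressure(t_mean)


def wind_speed(u, v):
    """Scalar wind speed from u/v components: sqrt(u^2 + v^2), m/s."""
    w = np.hypot(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
    return float(w) if w.ndim == 0 else w


# ---------------------------------------------------------------------------
# temperature bins


@dataclass(frozen=True)
class BinScheme:
    """An ordered partition of the temperature axis into labelled bins.

    ``edges`` are the interior cut points in deg C; bin k covers
    [edges[k-1], edges[k]) with the bottom bin open below and the top bin
    open above. ``reference_label`` names the comfort bin that serves as
    the omitted category in the regression.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]
    reference_label: str

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need exactly one more label than edges")
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("edges must be strictly increasing")
        if self.reference_label not in self.labels:
            raise ValueError("reference_label must be one of labels")

    @property
    def bounds(self) -> list[tuple[float, float, str]]:
        """(lower, upper, label) triples; infinities at the extremes."""
        lows = (-np.inf,) + self.edges
        highs = self.edges + (np.inf,)
        return list(zip(lows, highs, self.labels))

    @property
    def non_reference_labels(self) -> list[str]:
        return [lab for lab in self.labels if lab != self.reference_label]

    def assign(self, t_mean):
        """Bin label(s) for temperature(s); vectorized."""
        t = np.asarray(t_mean, dtype=float)
        idx = np.digitize(t, self.edges, right=False)
        labels = np.asarray(self.labels, dtype=object)
        out = labels[idx]
        return str(out) if t.ndim == 0 else pd.Categorical(
            out, categories=list(self.labels), ordered=True
        )

    @classmethod
    def full_10bin(cls) -> "BinScheme":
        """The main 10-bin scheme: <0, 0-3, ..., 24-27, >27 deg C."""
        return cls(
            edges=(0.0, 3.0, 6.0, 9.0, 12.0, 18.0, 21.0, 24.0, 27.0),
            labels=(
                "<0", "0-3", "3-6", "6-9", "9-12",
                "12-18", "18-21", "21-24", "24-27", ">27",
            ),
            reference_label="12-18",
        )

    @classmethod
    def germany_9bin(cls) -> "BinScheme":
        """The 9-bin variant for a milder climate: single >24 top bin."""
        return cls(
            edges=(0.0, 3.0, 6.0, 9.0, 12.0, 18.0, 21.0, 24.0),
            labels=(
                "<0", "0-3", "3-6", "6-9", "9-12",
                "12-18", "18-21", "21-24", ">24",
            ),
            reference_label="12-18",
        )

    @classmethod
    def from_name(cls, name: str) -> "BinScheme":
        schemes = {"full": cls.full_10bin, "germany": cls.germany_9bin}
        try:
            return schemes[name]()
        except KeyError:
            raise ValueError(
                f"unknown bin scheme {name!r}; choose from {sorted(schemes)}"
            ) from None


def assign_temp_bin(t_mean: float, scheme: BinScheme) -> str:
    """Label of the unique bin containing ``t_mean`` (lower-closed)."""
    return scheme.assign(float(t_mean))


def add_weather_features(
    weather: pd.DataFrame,
    scheme: BinScheme | None = None,
    t_col: str = "t_mean",
    dew_col: str = "t_dew",
    u_col: str = "u_wind",
    v_col: str = "v_wind",
) -> pd.DataFrame:
    """Augment a city-day weather table with rh, wind_speed and temp_bin."""
    scheme = scheme or BinScheme.full_10bin()
    out = weather.copy()
    out["rh"] = relative_humidity(out[t_col].to_numpy(), out[dew_col].to_numpy())
    out["wind_speed"] = wind_speed(out[u_col].to_numpy(), out[v_col].to_numpy())
    out["temp_bin"] = scheme.assign(out[t_col].to_numpy())
    return out


def add_exposure_lags(
    weather: pd.DataFrame,
    offsets: list[int],
    city_col: str = "city",
    date_col: str = "date",
    bin_col: str = "temp_bin",
) -> pd.DataFrame:
    """Add a shifted bin-label column per offset.

    For offset k the column ``temp_bin_lag{k}`` holds the bin label of
    date+k in the same city (k = -1 is the day before). A missing
    neighbour day yields a missing value, never a silently dropped row.
    """
    out = weather.copy()
    dates = pd.to_datetime(out[date_col])
    key = pd.MultiIndex.from_arrays([out[city_col], dates])
    lookup = pd.Series(np.asarray(out[bin_col], dtype=object), index=key)
    if not lookup.index.is_unique:
        raise ValueError("duplicate (city, date) rows in weather table")
    for k in offsets:
        shifted = pd.MultiIndex.from_arrays([out[city_col], dates + pd.Timedelta(days=k)])
        out[f"{bin_col}_lag{k}"] = lookup.reindex(shifted).to_numpy()
    return out


def binarize_covariate(value, threshold: float):
    """1 where value strictly exceeds threshold, 0 otherwise; NaN stays NaN.

    Used e.g. for the pollution flag: PM10 above the 50 ug/m3 guideline.
    """
    v = np.asarray(value, dtype=float)
    out = np.where(np.isnan(v), np.nan, (v > threshold).astype(float))
    return float(out) if out.ndim == 0 else out
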
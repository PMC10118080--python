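"""Bioactivity endpoints and their statistics.

Implements the three spectrophotometric assays used to characterise the
oils' bioactivity and the post-hoc statistics of the summary table:

* ABTS radical scavenging: %Reduction = (Ac - As)/Ac x 100; EC50 is the
  concentration at which the fitted dose-response curve crosses 50 %;
  TEAC expresses a sample's EC50 in Trolox equivalents (mg Trolox / kg oil).
* Total phenolic content (Folin-Ciocalteu, gallic-acid standard curve) and
  total carotenoid content (beta-carotene curve): ordinary least-squares
  calibration, absorbance inversion, unit conversion to mg analyte / kg oil.
* One-way ANOVA and all-pairs Tukey HSD from summary statistics
  (mean, SD, n per group), with a compact letter display built by
  insert-and-absorb; groups sharing a letter do not differ at alpha.

The dose-response model is a four-parameter logistic fitted with
``scipy.optimize.curve_fit``; when the fit fails or leaves > 5 % residual it
falls back to log-linear interpolation between the two points bracketing
50 %.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_data import AssayPlate

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- ABTS core

def percent_reduction(ac: float, as_: float) -> float:
    """Radical quenching: %Reduction = (Ac - As)/Ac x 100.

    Scale-invariant in (Ac, As); a negative value (pro-oxidant reading) is
    allowed but logged.
    """
    if ac <= 0:
        raise ValueError("control absorbance Ac must be positive")
    r = (ac - as_) / ac * 100.0
    if r < 0:
        log.warning("negative %%Reduction (%.2f): pro-oxidant reading", r)
    return r


def _logistic4(c, bottom, top, ec50m, hill):
    return bottom + (top - bottom) / (1.0 + (ec50m / np.maximum(c, 1e-300)) ** hill)


class EC50NotBracketed(ValueError):
    """Raised when the responses never span 50 %."""


def ec50(concentrations, responses, method: str = "auto") -> float:
    """Concentration at which the fitted dose-response curve crosses 50 %.

    ``responses`` are %reduction values on a rising curve.  Requires the
    observed responses to bracket 50 %.  ``method``: ``"auto"`` tries the
    four-parameter logistic and falls back to (log-)linear interpolation
    between the bracketing points when the fit fails or leaves more than 5 %
    of the response range as residual; ``"4pl"`` / ``"interpolate"`` force
    one route.
    """
    if method not in {"auto", "4pl", "interpolate"}:
        raise ValueError(f"unknown ec50 method {method!r}")
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) != len(r) or len(c) < 2:
        raise ValueError("need matched concentration/response arrays, length >= 2")
    order = np.argsort(c)
    c, r = c[order], r[order]
    if not (r.min() < 50.0 <= r.max() or r.min() <= 50.0 < r.max()):
        raise EC50NotBracketed("50% response not bracketed by the data")
    if np.polyfit(c, r, 1)[0] < 0:
        raise ValueError("dose-response must be increasing with concentration")

    fitted = None
    pos = c > 0
    if method != "interpolate" and pos.sum() >= 4:
        import warnings

        try:
            guess = float(c[pos][np.argmin(np.abs(r[pos] - 50.0))])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _logistic4,
                    c[pos],
                    r[pos],
                    p0=[max(r.min(), 0.0), min(r.max(), 100.0), guess, 1.0],
                    bounds=([-50.0, 0.0, 1e-12, 0.05], [100.0, 200.0, np.inf, 20.0]),
                    maxfev=20_000,
                )
            resid = np.sqrt(np.mean((r[pos] - _logistic4(c[pos], *popt)) ** 2))
            if method == "4pl" or resid <= 0.05 * max(np.ptp(r), 1.0):
                fitted = popt
        except (RuntimeError, ValueError):
            fitted = None
    if method == "4pl" and fitted is None:
        raise ValueError("four-parameter logistic fit failed")
    if fitted is not None:
        bottom, top, ec, hill = fitted
        if bottom < 50.0 < top:
            return float(ec * ((50.0 - bottom) / (top - 50.0)) ** (1.0 / hill))
    # fall back: (log-)linear interpolation between the bracketing points
    above = np.flatnonzero(r >= 50.0)
    below = np.flatnonzero(r < 50.0)
    i_hi = above[0]
    i_lo = below[below < i_hi][-1] if len(below[below < i_hi]) else i_hi - 1
    c_lo, c_hi = c[i_lo], c[i_hi]
    r_lo, r_hi = r[i_lo], r[i_hi]
    if r_hi == r_lo:
        return float(c_hi)
    frac = (50.0 - r_lo) / (r_hi - r_lo)
    if c_lo > 0 and c_hi > 0:
        return float(np.exp(np.log(c_lo) + frac * (np.log(c_hi) - np.log(c_lo))))
    return float(c_lo + frac * (c_hi - c_lo))


def teac(ec50_sample: float, ec50_trolox: float) -> float:
    """Trolox-equivalent antioxidant capacity.

    With the sample EC50 in kg oil per litre of assay and the Trolox EC50 in
    mg per litre, the ratio lands directly in mg Trolox per kg oil.
    """
    if ec50_sample <= 0 or ec50_trolox <= 0:
        raise ValueError("EC50 values must be positive")
    return ec50_trolox / ec50_sample


# ----------------------------------------------------------- standard curves

@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float

    def invert(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


def standard_curve(points) -> StandardCurve:
    """OLS calibration line over (concentration, absorbance) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("standard curve needs >= 2 (conc, absorbance) points")
    conc, absb = pts[:, 0], pts[:, 1]
    res = stats.linregress(conc, absb)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
    )


def concentration_from_absorbance(
    curve: StandardCurve,
    absorbance: float,
    dilution: float = 1.0,
    oil_concentration: float | None = None,
) -> float:
    """Invert a calibration line to analyte concentration.

    Returns ug/ml in the measured solution times ``dilution``; when the oil
    concentration in the assay (kg oil / l) is given, the result is converted
    to mg analyte per kg oil.  Readings outside the calibrated range are
    flagged with a warning (extrapolation).
    """
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    raw = curve.invert(absorbance)
    if not curve.conc_min <= raw <= curve.conc_max:
        log.warning(
            "absorbance %.4f inverts to %.3f ug/ml, outside the calibrated "
            "range [%.3f, %.3f] (extrapolation)",
            absorbance, raw, curve.conc_min, curve.conc_max,
        )
    value = raw * dilution
    if oil_concentration is not None:
        if oil_concentration <= 0:
            raise ValueError("oil concentration must be positive")
        value = value / oil_concentration  # (ug/ml == mg/l) / (kg/l) -> mg/kg
    return float(value)


# ------------------------------------------------------------ plate analysis

def abts_analyze(sample_plate: AssayPlate, trolox_plate: AssayPlate) -> float:
    """TEAC (mg Trolox / kg oil) from a pair of simulated ABTS plates."""
    ac = sample_plate.control_absorbance

    def plate_ec50(plate: AssayPlate) -> float:
        As = np.asarray(plate.sample_absorbances, dtype=float).mean(axis=0)
        red = np.array([percent_reduction(plate.control_absorbance, a) for a in As])
        return ec50(plate.sample_concentrations, red)

    if ac is None:
        raise ValueError("ABTS plate lacks a control absorbance")
    return teac(plate_ec50(sample_plate), plate_ec50(trolox_plate))


def linear_assay_analyze(plate: AssayPlate) -> float:
    """TPC or TCC (mg analyte / kg oil) from a simulated calibration plate.

    Replicates are converted to concentration individually and averaged;
    absorbances are blank-subtracted before inversion.
    """
    std = np.column_stack(
        [
            plate.standard_concentrations,
            np.asarray(plate.standard_absorbances, dtype=float) - plate.blank_absorbance,
        ]
    )
    curve = standard_curve(std)
    values = [
        concentration_from_absorbance(
            curve,
            a - plate.blank_absorbance,
            dilution=plate.dilution,
            oil_concentration=plate.oil_concentration,
        )
        for a in np.atleast_1d(plate.sample_absorbances)
    ]
    return float(np.mean(values))


# ------------------------------------------------- ANOVA + Tukey HSD letters

@dataclass
class TukeyResult:
    groups: list[str]
    means: np.ndarray
    letters: dict[str, str]
    p_matrix: pd.DataFrame
    f_statistic: float
    p_anova: float
    mse: float
    df_error: int


def anova_tukey(groups: pd.DataFrame, alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA + Tukey HSD from per-group summary statistics.

    ``groups`` needs columns ``group``, ``mean``, ``sd``, ``n``.  The pooled
    error mean square is sum((n_i - 1) s_i^2) / sum(n_i - 1); pairwise
    comparisons use the studentized-range statistic at the pooled error df.
    Letters are assigned from the highest mean down (``a`` = top group).
    """
    df = groups.reset_index(drop=True)
    required = {"group", "mean", "sd", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    k = len(df)
    if k < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    if (df["n"] < 2).any():
        raise ValueError("each group needs n >= 2 replicates")
    n = df["n"].to_numpy(dtype=float)
    m = df["mean"].to_numpy(dtype=float)
    s = df["sd"].to_numpy(dtype=float)
    df_err = int((n - 1).sum())
    mse = float(((n - 1) * s**2).sum() / (n - 1).sum())
    if mse <= 0:
        raise ValueError("zero pooled variance: Tukey statistic undefined")

    grand = (n * m).sum() / n.sum()
    ss_between = float((n * (m - grand) ** 2).sum())
    ms_between = ss_between / (k - 1)
    f_stat = ms_between / mse
    p_anova = float(stats.f.sf(f_stat, k - 1, df_err))

    names = df["group"].astype(str).tolist()
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
            q = abs(m[i] - m[j]) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
            P[i, j] = P[j, i] = p

    letters = _compact_letter_display(names, m, P, alpha)
    return TukeyResult(
        groups=names,
        means=m,
        letters=letters,
        p_matrix=pd.DataFrame(P, index=names, columns=names),
        f_statistic=float(f_stat),
        p_anova=p_anova,
        mse=mse,
        df_error=df_err,
    )


def _compact_letter_display(
    names: list[str], means: np.ndarray, P: np.ndarray, alpha: float
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one letter covering every group; for each significant pair,
    split every letter column containing both; absorb columns that became
    subsets of others.  Letters are ordered so that ``a`` belongs to the
    highest mean.
    """
    order = np.argsort(-means, kind="stable")
    k = len(names)
    columns: list[set[int]] = [set(range(k))]
    sig_pairs = [
        (i, j) for i in range(k) for j in range(i + 1, k) if P[i, j] < alpha
    ]
    for i, j in sig_pairs:
        new_cols = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb: drop any column that is a subset of another
        columns = []
        for col in new_cols:
            if not col:
                continue
            if any(col < other for other in new_cols if other is not col):
                continue
            if col in columns:
                continue
            columns.append(col)
    # order columns by the rank of their best (highest-mean) member
    rank = {int(g): r for r, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {name: "" for name in names}
    for li, col in enumerate(columns):
        symbol = string.ascii_lowercase[li % 26] * (1 + li // 26)
        for g in sorted(col, key=lambda g: rank[g]):
            letters[names[g]] += symbol
    if any(not v for v in letters.values()):
        raise AssertionError("compact letter display left a group unlabelled")
    return letters


def letters_consistent(result: TukeyResult, alpha: float = 0.05) -> bool:
    """Validity check: two groups share a letter iff their Tukey p >= alpha."""
    for i, gi in enumerate(result.groups):
        for j in range(i + 1, len(result.groups)):
            gj = result.groups[j]
            share = bool(set(result.letters[gi]) & set(result.letters[gj]))
            if share != (result.p_matrix.iloc[i, j] >= alpha):
                return False
    return True
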
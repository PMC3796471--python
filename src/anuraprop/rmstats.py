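"""Repeated-measures inference for the excess-attenuation designs.

Both analyses are split-plot (mixed) designs: subjects carry one
between-subjects factor (frequency category for the tone analysis, species
for the call analysis) and are measured under the complete crossing of three
within-subject factors (distance × substrate × locality). The univariate
decomposition works on orthonormal within-cell contrasts: for a within
effect with contrast matrix C (cells × q, orthonormal, orthogonal to the
unit vector), the per-subject score matrix Z = Y·C yields

    SS_effect       = N ·  ||z̄||²                     (df q)
    SS_effect×group = Σ_g n_g ||z̄_g − z̄||²            (df q(g−1))
    SS_error        = Σ_g Σ_{s∈g} ||z_s − z̄_g||²      (df q(N−g))

which reproduces the classical split-plot sums of squares. Sphericity
diagnostics (Mauchly's W) and the Greenhouse–Geisser / Huynh–Feldt epsilons
come from the pooled within-group covariance of Z in the same stratum; the
Huynh–Feldt correction rescales the F-test's degrees of freedom. Corrected
p-values are reported when Mauchly's test rejects sphericity (p < 0.05),
with a flag to force always-corrected output.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# response transform

def transform_response(values, method: str = "shifted_log"):
    """Monotone transform applied to EA (dB) before inference.

    "shifted_log": log(v − min(v) + 1), handles negative dB values;
    "identity": no transform; "linear_log": log of the linear-scale pressure
    ratio, i.e. v·ln(10)/20 (an affine map of the dB values).
    Returns (transformed, info) where info records the method and shift so
    the transform can be inverted.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("transform_response requires finite values")
    if method == "identity":
        return v.copy(), {"method": method}
    if method == "shifted_log":
        shift = float(np.min(v))
        return np.log(v - shift + 1.0), {"method": method, "shift": shift}
    if method == "linear_log":
        return v * (np.log(10.0) / 20.0), {"method": method}
    raise ValueError(f"unknown transform {method!r}")


def inverse_transform(values, info: dict):
    v = np.asarray(values, dtype=float)
    m = info["method"]
    if m == "identity":
        return v.copy()
    if m == "shifted_log":
        return np.exp(v) - 1.0 + info["shift"]
    if m == "linear_log":
        return v * (20.0 / np.log(10.0))
    raise ValueError(f"unknown transform {m!r}")


# ---------------------------------------------------------------------------
# contrasts

@lru_cache(maxsize=None)
def _orthonormal_contrast(k: int) -> np.ndarray:
    """k×(k−1) orthonormal basis of the complement of the unit vector."""
    if k < 2:
        raise ValueError("factor needs >= 2 levels")
    a = np.eye(k) - np.ones((k, k)) / k
    q, r = np.linalg.qr(a)
    cols = q[:, np.abs(np.diag(r)) > 1e-10]
    return cols[:, :k - 1]


def _effect_contrast(levels: tuple[int, ...], active: tuple[int, ...]) -> np.ndarray:
    """Kronecker contrast over the within-cell grid.

    ``levels`` are the within-factor level counts in cell order (slowest
    varying first); ``active`` indexes the factors participating in the
    effect (others are averaged via the normalized unit vector).
    """
    mats = []
    for i, k in enumerate(levels):
        if i in active:
            mats.append(_orthonormal_contrast(k))
        else:
            mats.append(np.full((k, 1), 1.0 / np.sqrt(k)))
    c = mats[0]
    for m in mats[1:]:
        c = np.kron(c, m)
    return c


# ---------------------------------------------------------------------------
# sphericity

def _mauchly_from_cov(sigma: np.ndarray, n_e: int) -> tuple[float, float]:
    """Mauchly's W and chi-square p from the q×q contrast-score covariance
    pooled on n_e error df."""
    q = sigma.shape[0]
    if q < 2:
        return 1.0, 1.0
    eig = np.linalg.eigvalsh(sigma)
    eig = np.clip(eig, 0.0, None)
    mean_eig = np.mean(eig)
    if mean_eig <= 0 or np.any(eig <= 0) or n_e <= q:
        return 0.0, float("nan")  # singular pooled covariance
    w = float(np.exp(np.sum(np.log(eig)) - q * np.log(mean_eig)))
    # Box's chi-square series to second order (as in ezANOVA/pingouin),
    # with the pooled error df in place of n−1
    f = 1.0 - (2.0 * q**2 + q + 2.0) / (6.0 * q * n_e)
    w2 = ((q + 2.0) * (q - 1.0) * (q - 2.0)
          * (2.0 * q**3 + 6.0 * q**2 + 3.0 * (q + 1.0) + 2.0)
          / (288.0 * (n_e * q * f) ** 2))
    chi2 = -n_e * f * np.log(max(w, 1e-300))
    df = q * (q + 1) // 2 - 1
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    return w, float(p1 + w2 * (p2 - p1))


def _epsilons(sigma: np.ndarray, n_subjects: int, n_groups: int
              ) -> tuple[float, float]:
    """(Greenhouse–Geisser, Huynh–Feldt) epsilons from the orthonormal
    contrast-score covariance; HF truncated at 1, both floored at 1/q."""
    q = sigma.shape[0]
    if q < 2:
        return 1.0, 1.0
    tr = np.trace(sigma)
    tr2 = np.trace(sigma @ sigma)
    if tr2 <= 0:
        return 1.0, 1.0
    gg = float(tr**2 / (q * tr2))
    gg = min(max(gg, 1.0 / q), 1.0)
    num = (n_subjects - n_groups + 1) * q * gg - 2.0
    den = q * (n_subjects - n_groups - q * gg)
    hf = gg if den <= 0 else num / den
    hf = min(max(hf, gg), 1.0)
    return gg, hf


def mauchly_test(data, within_factor: str | None = None,
                 subject: str = "subject", value: str = "value"
                 ) -> tuple[float, float]:
    """Mauchly's sphericity test.

    ``data`` may be a wide array (subjects × levels) or a tidy DataFrame
    with ``subject``, ``within_factor`` and ``value`` columns. Two-level
    factors are trivially spherical: (W, p) = (1, 1).
    """
    if isinstance(data, pd.DataFrame):
        wide = data.pivot_table(index=subject, columns=within_factor,
                                values=value).to_numpy()
    else:
        wide = np.asarray(data, dtype=float)
    n, k = wide.shape
    if k < 3:
        return 1.0, 1.0
    c = _orthonormal_contrast(k)
    z = wide @ c
    sigma = np.cov(z, rowvar=False, ddof=1)
    return _mauchly_from_cov(sigma, n - 1)


# ---------------------------------------------------------------------------
# the mixed ANOVA

@dataclass
class RmDesign:
    """Design description for the split-plot ANOVA on tidy data."""

    subject: str
    between: str
    within: tuple[str, ...]  # complete crossing required per subject
    response: str = "excess_attenuation"


def _pivot_design(data: pd.DataFrame, design: RmDesign):
    """Tidy → (Y wide array, group codes, group labels, within level lists)."""
    within = list(design.within)
    levels = {w: sorted(data[w].unique().tolist()) for w in within}
    pivot = data.pivot_table(index=design.subject, columns=within,
                             values=design.response, aggfunc="mean")
    full_cols = pd.MultiIndex.from_product([levels[w] for w in within],
                                           names=within) \
        if len(within) > 1 else pd.Index(levels[within[0]], name=within[0])
    missing = [c for c in full_cols if c not in pivot.columns]
    if missing or pivot.isna().any().any():
        bad = missing or pivot.columns[pivot.isna().any()].tolist()
        raise ValueError(f"incomplete within-subject crossing; missing cells: "
                         f"{bad[:5]}{'...' if len(bad) > 5 else ''}")
    pivot = pivot.reindex(columns=full_cols)
    groups = data.drop_duplicates(design.subject).set_index(design.subject)[
        design.between].reindex(pivot.index)
    if groups.isna().any():
        raise ValueError("every subject needs a between-factor level")
    labels = sorted(groups.unique().tolist())
    codes = groups.map({g: i for i, g in enumerate(labels)}).to_numpy()
    return (pivot.to_numpy(dtype=float), codes, labels,
            tuple(len(levels[w]) for w in within))


def rm_anova(data: pd.DataFrame, design: RmDesign, *,
             alpha_sphericity: float = 0.05,
             always_correct: bool = False,
             epsilon: str = "hf",
             transform: str | None = None) -> pd.DataFrame:
    """Four-way split-plot ANOVA table (one between + up to three within
    factors, all two-way interactions), with per-stratum sphericity
    diagnostics and Huynh–Feldt-corrected p-values.

    Returns one row per effect with F, df_num, df_den, p_uncorrected,
    epsilon_hf, p_hf, mauchly_w, mauchly_p, shapiro_p and p_reported (the
    corrected p when sphericity failed, the uncorrected p otherwise).
    """
    data = data.copy()
    if transform and transform != "identity":
        data[design.response], _ = transform_response(
            data[design.response].to_numpy(), transform)
    y, codes, labels, levels = _pivot_design(data, design)
    return _rm_anova_wide(y, codes, levels,
                          between_name=design.between,
                          within_names=design.within,
                          alpha_sphericity=alpha_sphericity,
                          always_correct=always_correct,
                          epsilon=epsilon)


def _shapiro_p(resid: np.ndarray) -> float:
    r = np.asarray(resid, dtype=float).ravel()
    if len(r) < 3:
        return float("nan")
    if len(r) > 4500:  # scipy's shapiro is calibrated for moderate n
        r = r[:: len(r) // 4500 + 1]
    if np.ptp(r) == 0:
        return float("nan")
    return float(stats.shapiro(r).pvalue)


def _rm_anova_wide(y: np.ndarray, codes: np.ndarray, levels: tuple[int, ...],
                   *, between_name: str = "group",
                   within_names: tuple[str, ...] = ("w1", "w2", "w3"),
                   alpha_sphericity: float = 0.05,
                   always_correct: bool = False,
                   epsilon: str = "hf") -> pd.DataFrame:
    """Core numeric path: ``y`` is subjects × within-cells (cell order =
    product of ``levels``, slowest first), ``codes`` the group index."""
    n, p = y.shape
    g = int(codes.max()) + 1
    n_g = np.bincount(codes, minlength=g).astype(float)
    rows = []

    # between-subjects stratum: one-way ANOVA on subject means, scaled by p
    u = y.mean(axis=1)
    grand = u.mean()
    gmeans = np.array([u[codes == j].mean() for j in range(g)])
    if g > 1:
        ss_b = p * float(np.sum(n_g * (gmeans - grand) ** 2))
        resid_u = u - gmeans[codes]
        ss_s = p * float(np.sum(resid_u**2))
        df_b, df_s = g - 1, n - g
        f_b = (ss_b / df_b) / (ss_s / df_s)
        p_b = float(stats.f.sf(f_b, df_b, df_s))
        rows.append({"effect": between_name, "F": f_b, "df_num": df_b,
                     "df_den": df_s, "p_uncorrected": p_b, "epsilon_hf": 1.0,
                     "p_hf": p_b, "mauchly_w": 1.0, "mauchly_p": 1.0,
                     "shapiro_p": _shapiro_p(resid_u), "p_reported": p_b,
                     "corrected": False})

    # within strata: main effects and all two-way interactions
    effects: list[tuple[str, tuple[int, ...], bool]] = []
    for i, w in enumerate(within_names):
        effects.append((w, (i,), False))                       # main
        if g > 1:
            effects.append((f"{w} * {between_name}", (i,), True))
    for (i, wi), (j, wj) in combinations(enumerate(within_names), 2):
        effects.append((f"{wi} * {wj}", (i, j), False))

    for name, active, with_between in effects:
        c = _effect_contrast(levels, active)
        q = c.shape[1]
        z = y @ c
        zbar = z.mean(axis=0)
        zg = np.array([z[codes == j].mean(axis=0) for j in range(g)])
        resid = z - zg[codes]
        e_trace = float(np.sum(resid**2))
        df_err = q * (n - g)
        sigma = (resid.T @ resid) / (n - g)
        w_m, p_m = _mauchly_from_cov(sigma, n - g)
        eps_gg, eps_hf = _epsilons(sigma, n, g)
        if epsilon == "gg":  # Greenhouse–Geisser behind a flag, never default
            eps_hf = eps_gg
        if with_between:
            ss = float(np.sum(n_g[:, None] * (zg - zbar) ** 2))
            df_num = q * (g - 1)
        else:
            ss = n * float(np.sum(zbar**2))
            df_num = q
        f_val = (ss / df_num) / (e_trace / df_err)
        p_unc = float(stats.f.sf(f_val, df_num, df_err))
        p_hf = float(stats.f.sf(f_val, df_num * eps_hf, df_err * eps_hf))
        corrected = always_correct or (q > 1 and np.isfinite(p_m)
                                       and p_m < alpha_sphericity)
        rows.append({"effect": name, "F": f_val, "df_num": df_num,
                     "df_den": df_err, "p_uncorrected": p_unc,
                     "epsilon_hf": eps_hf, "p_hf": p_hf, "mauchly_w": w_m,
                     "mauchly_p": p_m, "shapiro_p": _shapiro_p(resid),
                     "p_reported": p_hf if corrected else p_unc,
                     "corrected": corrected})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise comparisons

def bonferroni_pairwise(data: pd.DataFrame, factor: str, *,
                        subject: str = "subject",
                        response: str = "excess_attenuation",
                        paired: bool = True) -> pd.DataFrame:
    """All level pairs of ``factor`` with Bonferroni-corrected p-values
    (corrected p = min(1, m·p_raw), m = number of pairs). Within-subject
    factors use paired t-tests on per-subject cell means; between-subject
    factors independent t-tests."""
    levels = sorted(data[factor].unique().tolist())
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    cell = data.groupby([subject, factor])[response].mean().unstack(factor)
    rows = []
    for a, b in pairs:
        if paired:
            t, p_raw = stats.ttest_rel(cell[a], cell[b])
        else:
            t, p_raw = stats.ttest_ind(cell[a].dropna(), cell[b].dropna())
        rows.append({"level_a": a, "level_b": b, "t": float(t),
                     "p_raw": float(p_raw),
                     "p_bonferroni": float(min(1.0, m * p_raw)),
                     "n_comparisons": m})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation helpers (null calibration / power checks)

def simulate_null_wide(group_sizes, levels: tuple[int, ...],
                       rng: np.random.Generator,
                       effect: np.ndarray | None = None):
    """IID standard-normal split-plot data (spherical covariance, no
    effects); optionally adds a fixed within-cell effect vector."""
    n = int(np.sum(group_sizes))
    p = int(np.prod(levels))
    y = rng.standard_normal((n, p))
    if effect is not None:
        y = y + np.asarray(effect, dtype=float)[None, :]
    codes = np.repeat(np.arange(len(group_sizes)), group_sizes)
    return y, codes


def tone_design_groups() -> list[int]:
    """Between-group sizes of the tone analysis: number of probe tones per
    frequency category (F1–F5)."""
    from .attenuation import bin_frequency
    from .signals import generate_tone_schedule
    counts: dict[str, int] = {}
    for spec in generate_tone_schedule():
        cat = bin_frequency(spec.frequency)
        counts[cat] = counts.get(cat, 0) + 1
    return [counts[k] for k in sorted(counts)]


def null_rejection_rates(n_reps: int = 1000, seed: int = 0, *,
                         group_sizes=None, levels: tuple[int, ...] = (4, 2, 7),
                         within_names: tuple[str, ...] = ("distance",
                                                          "substrate",
                                                          "locality"),
                         between_name: str = "frequency_category",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Monte-Carlo null calibration of the reported (sphericity-gated,
    Huynh–Feldt-corrected) p-values: per-effect rejection rate at ``alpha``
    under iid normal data."""
    if group_sizes is None:
        group_sizes = tone_design_groups()
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    table = None
    for _ in range(n_reps):
        y, codes = simulate_null_wide(group_sizes, levels, rng)
        table = _rm_anova_wide(y, codes, levels, between_name=between_name,
                               within_names=within_names)
        for _, row in table.iterrows():
            counts[row["effect"]] = counts.get(row["effect"], 0) + \
                (1 if row["p_reported"] < alpha else 0)
    out = pd.DataFrame({"effect": list(counts),
                        "rejection_rate": [counts[e] / n_reps for e in counts],
                        "n_reps": n_reps})
    if table is not None:
        out = out.merge(table[["effect", "df_num", "df_den"]], on="effect")
    return out
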
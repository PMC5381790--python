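"""Matching-symmetry analysis: directional and fluctuating asymmetry.

For paired bilateral structures, the right side is reflected (x -> -x by
default) so its landmarks correspond to the left side, and both sides are
jointly superimposed ("matching symmetry").  A Procrustes ANOVA on the
tangent-space shape variables then decomposes variation into

* ``Individual``       — genuine among-individual shape variation,
* ``Side``             — directional asymmetry (DA), a consistent mean
                         left-right difference, tested against the
                         individual x side interaction,
* ``Individual x Side``— fluctuating asymmetry (FA), random individual
                         left-right deviations, tested against digitising
                         (measurement) error,
* ``Measurement error``— variation between digitising sessions.

P-values come from residual randomisation under the reduced model (RRPP):
for each term, residuals of the model without that term are permuted and
the term's F recomputed; P = (#{F* >= F} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmarks import AlignedSet, Configuration, ConfigurationSet
from .procrustes import gpa, project_to_tangent, slide_semilandmarks

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "AsymmetryResult",
    "reflect_side",
    "matching_alignment",
    "procrustes_anova",
    "measurement_error_anova",
    "decompose_asymmetry",
    "per_landmark_asymmetry",
]


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    df: int
    SS: float
    MS: float
    F: float | None = None
    P: float | None = None


@dataclass
class AnovaTable:
    """Effect / df / SS / MS / F / P decomposition of shape variation."""

    rows: list[AnovaRow]
    total_SS: float
    n_perm: int
    seed: int | None = None

    def __post_init__(self) -> None:
        ss_sum = sum(r.SS for r in self.rows)
        if self.total_SS > 0 and abs(ss_sum - self.total_SS) > 1e-9 * self.total_SS:
            raise ValueError(
                f"SS rows sum to {ss_sum}, expected total {self.total_SS}"
            )

    def __getitem__(self, effect: str) -> AnovaRow:
        for r in self.rows:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": r.effect, "df": r.df, "SS": r.SS, "MS": r.MS, "F": r.F, "P": r.P}
                for r in self.rows
            ]
        )


@dataclass
class AsymmetryResult:
    """Procrustes-ANOVA asymmetry decomposition plus DA/FA summaries."""

    anova: AnovaTable
    da_vector: np.ndarray          # consensus L minus reflected-R displacement, k x d
    fa_scores: np.ndarray          # per-individual signed asymmetry deviations, n x (k*d)
    individuals: list[str]
    da_significant: bool
    fa_significant: bool
    alpha: float = 0.05


def reflect_side(config: Configuration, axis: int = 0) -> Configuration:
    """Mirror a configuration by negating one coordinate (default x).

    Metadata is unchanged except the ``reflected`` flag, which toggles so
    that reflecting twice restores the original configuration exactly.
    """
    if not (0 <= axis < config.dims):
        raise ValueError(f"axis {axis} invalid for {config.dims}-dimensional data")
    coords = config.coords.copy()
    coords[:, axis] = -coords[:, axis]
    return config.with_coords(coords, reflected=not config.reflected)


def matching_alignment(
    cset: ConfigurationSet,
    do_scale: bool = True,
    slide: bool = True,
    reflect_axis: int = 0,
) -> AlignedSet:
    """Reflect every right-side configuration and jointly superimpose both
    sides (GPA, then semi-landmark sliding when the scheme has chains,
    then tangent projection).

    Raises
    ------
    ValueError
        If any individual lacks one of the two sides.
    """
    sides_by_ind: dict[str, set[str]] = {}
    for c in cset:
        sides_by_ind.setdefault(c.individual, set()).add(c.side)
    missing = sorted(i for i, s in sides_by_ind.items() if s != {"L", "R"})
    if missing:
        raise ValueError(f"individuals missing a side: {missing}")

    reflected = ConfigurationSet(
        cset.scheme,
        [reflect_side(c, reflect_axis) if c.side == "R" else c for c in cset],
    )
    aligned = gpa(reflected, do_scale=do_scale)
    if slide and cset.scheme.chains:
        aligned = slide_semilandmarks(aligned)
    return project_to_tangent(aligned)


def _design_codes(aligned: AlignedSet):
    """Individual / side / replicate integer codes; enforce a balanced
    fully crossed individual x side x replicate design."""
    inds = aligned.source.individuals()
    ind_index = {k: i for i, k in enumerate(inds)}
    ind = np.array([ind_index[c.individual] for c in aligned.source])
    side = np.array([0 if c.side == "L" else 1 for c in aligned.source])
    n, s = len(inds), 2
    counts = np.zeros((n, s), dtype=int)
    np.add.at(counts, (ind, side), 1)
    if counts.min() == 0 or counts.max() != counts.min():
        raise ValueError(
            "unbalanced design: every individual needs both sides with an "
            "equal number of replicates"
        )
    r = int(counts[0, 0])
    return inds, ind, side, n, s, r


def _anova_terms(Y: np.ndarray, ind: np.ndarray, side: np.ndarray, n: int, s: int, r: int):
    """Sequential sums of squares of the balanced crossed design."""
    grand = Y.mean(axis=0)
    cell = np.zeros((n * s, Y.shape[1]))
    np.add.at(cell, ind * s + side, Y)
    cell /= r
    cell3 = cell.reshape(n, s, -1)
    mean_i = cell3.mean(axis=1)
    mean_s = cell3.mean(axis=0)
    ss_ind = s * r * float(np.sum((mean_i - grand) ** 2))
    ss_side = n * r * float(np.sum((mean_s - grand) ** 2))
    inter = cell3 - mean_i[:, None, :] - mean_s[None, :, :] + grand
    ss_int = r * float(np.sum(inter**2))
    ss_err = float(np.sum((Y - cell[ind * s + side]) ** 2))
    return ss_ind, ss_side, ss_int, ss_err, grand, mean_i, mean_s, cell


def procrustes_anova(
    aligned: AlignedSet,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnovaTable:
    """Procrustes ANOVA of a matching-symmetry alignment.

    Sums of squares are summed squared tangent-space deviations assigned
    sequentially to Individual, Side, Individual x Side and (with >= 2
    digitising sessions) Measurement error.  F ratios follow the mixed
    model: Individual and Side are tested over the interaction, the
    interaction over measurement error.  P by RRPP permutation.
    """
    if aligned.tangent is None:
        raise ValueError("project_to_tangent must be run before the ANOVA")
    inds, ind, side, n, s, r = _design_codes(aligned)
    Y = aligned.tangent
    ss_ind, ss_side, ss_int, ss_err, grand, mean_i, mean_s, _ = _anova_terms(
        Y, ind, side, n, s, r
    )
    df_ind, df_side, df_int, df_err = n - 1, s - 1, (n - 1) * (s - 1), n * s * (r - 1)
    ms_ind, ms_side, ms_int = ss_ind / df_ind, ss_side / df_side, ss_int / df_int
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    f_ind = ms_ind / ms_int
    f_side = ms_side / ms_int
    f_int = ms_int / ms_err if df_err > 0 else None

    rng = np.random.default_rng(seed)
    n_obs = Y.shape[0]

    def _rrpp(fitted_reduced, f_obs, statistic) -> float:
        resid = Y - fitted_reduced
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_obs)
            Y_star = fitted_reduced + resid[perm]
            if statistic(Y_star) >= f_obs - 1e-12:
                count += 1
        return (count + 1) / (n_perm + 1)

    def _f_side(Y_star):
        a, b, c, d, *_ = _anova_terms(Y_star, ind, side, n, s, r)
        return (b / df_side) / (c / df_int)

    def _f_ind(Y_star):
        a, b, c, d, *_ = _anova_terms(Y_star, ind, side, n, s, r)
        return (a / df_ind) / (c / df_int)

    def _f_int(Y_star):
        a, b, c, d, *_ = _anova_terms(Y_star, ind, side, n, s, r)
        return (c / df_int) / (d / df_err)

    p_ind = _rrpp(np.broadcast_to(grand, Y.shape), f_ind, _f_ind)
    p_side = _rrpp(mean_i[ind], f_side, _f_side)
    p_int = None
    if df_err > 0:
        fitted_add = mean_i[ind] + mean_s[side] - grand
        p_int = _rrpp(fitted_add, f_int, _f_int)

    rows = [
        AnovaRow("Individual", df_ind, ss_ind, ms_ind, f_ind, p_ind),
        AnovaRow("Side", df_side, ss_side, ms_side, f_side, p_side),
        AnovaRow("Individual × Side", df_int, ss_int, ms_int, f_int, p_int),
    ]
    total = ss_ind + ss_side + ss_int
    if df_err > 0:
        rows.append(AnovaRow("Measurement error", df_err, ss_err, ms_err))
        total += ss_err
    return AnovaTable(rows=rows, total_SS=total, n_perm=n_perm, seed=seed)


def measurement_error_anova(
    aligned: AlignedSet, n_perm: int = 999, seed: int | None = None
) -> AnovaTable:
    """One-side Procrustes ANOVA of individuals vs digitising sessions.

    Quantifies the shape variation attributable to landmark positioning:
    ``Individual`` is tested against the between-session residual; the
    R-squared of interest is ``SS_individual / SS_total``.
    """
    if aligned.tangent is None:
        raise ValueError("project_to_tangent must be run before the ANOVA")
    inds = aligned.source.individuals()
    ind_index = {k: i for i, k in enumerate(inds)}
    ind = np.array([ind_index[c.individual] for c in aligned.source])
    reps = np.bincount(ind)
    if reps.min() < 2 or reps.max() != reps.min():
        raise ValueError("each individual needs the same number (>= 2) of sessions")
    r = int(reps[0])
    n = len(inds)
    Y = aligned.tangent
    grand = Y.mean(axis=0)
    mean_i = np.zeros((n, Y.shape[1]))
    np.add.at(mean_i, ind, Y)
    mean_i /= r
    ss_ind = r * float(np.sum((mean_i - grand) ** 2))
    ss_err = float(np.sum((Y - mean_i[ind]) ** 2))
    df_ind, df_err = n - 1, n * (r - 1)
    ms_ind, ms_err = ss_ind / df_ind, ss_err / df_err
    f_obs = ms_ind / ms_err

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        Yp = Y[perm]
        mi = np.zeros_like(mean_i)
        np.add.at(mi, ind, Yp)
        mi /= r
        ssi = r * float(np.sum((mi - grand) ** 2))
        sse = float(np.sum((Yp - mi[ind]) ** 2))
        if (ssi / df_ind) / (sse / df_err) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    rows = [
        AnovaRow("Individual", df_ind, ss_ind, ms_ind, f_obs, p),
        AnovaRow("Measurement error", df_err, ss_err, ms_err),
    ]
    return AnovaTable(rows=rows, total_SS=ss_ind + ss_err, n_perm=n_perm, seed=seed)


def _individual_side_deviations(aligned: AlignedSet):
    """Per-individual L minus reflected-R deviation (replicate-averaged),
    as an n_individuals x k x d array, plus individual order and sites."""
    inds, ind, side, n, s, r = _design_codes(aligned)
    k, d = aligned.consensus.shape
    acc = np.zeros((n, s, k, d))
    np.add.at(acc, (ind, side), aligned.proc_coords)
    acc /= r
    dev = acc[:, 0] - acc[:, 1]  # L - reflected R
    sites = [None] * n
    for c, i in zip(aligned.source, ind):
        sites[i] = c.site
    return dev, inds, sites


def decompose_asymmetry(
    aligned: AlignedSet,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> AsymmetryResult:
    """Full DA/FA decomposition of a matching-symmetry alignment.

    Runs :func:`procrustes_anova` with the asymmetry error-term map and
    extracts the consensus directional-asymmetry displacement per landmark
    and per-individual fluctuating-asymmetry deviations (which sum to the
    zero vector).
    """
    _, _, _, _, _, r = _design_codes(aligned)
    if r < 2:
        raise ValueError(
            "fluctuating-asymmetry testing requires >= 2 digitising sessions "
            "(measurement error is its error term)"
        )
    anova = procrustes_anova(aligned, n_perm=n_perm, seed=seed)
    dev, inds, _ = _individual_side_deviations(aligned)
    da_vector = dev.mean(axis=0)
    fa = (dev - da_vector).reshape(len(inds), -1)
    side_row = anova["Side"]
    int_row = anova["Individual × Side"]
    return AsymmetryResult(
        anova=anova,
        da_vector=da_vector,
        fa_scores=fa,
        individuals=inds,
        da_significant=bool(side_row.P is not None and side_row.P < alpha),
        fa_significant=bool(int_row.P is not None and int_row.P < alpha),
        alpha=alpha,
    )


def per_landmark_asymmetry(
    aligned: AlignedSet,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test each landmark's mean left-right deviation, controlling for site.

    For every landmark the per-individual L minus reflected-R deviation
    (a d-vector) is the response; site enters as a conditioning factor
    (centered dummy coding, so it absorbs between-site differences without
    touching the overall mean).  The reported statistic is the
    Ezekiel-adjusted pure fraction of (uncentered) variance explained by
    the mean offset; the permutation null flips the sign of each
    individual's site-adjusted deviation, which is the exchangeability
    implied by the no-asymmetry hypothesis.

    Returns a tidy frame: landmark, R2_adj, P, P_adj (Benjamini-Hochberg).
    """
    from statsmodels.stats.multitest import multipletests

    dev, inds, sites = _individual_side_deviations(aligned)
    n, k, d = dev.shape
    site_levels = sorted({s for s in sites if s is not None})
    if len(site_levels) < 2:
        if any(s is not None for s in sites):
            warnings.warn("fewer than 2 sites: falling back to the uncontrolled test")
        Zc = None
        g = 1
    else:
        Z = np.zeros((n, len(site_levels) - 1))
        for i, s in enumerate(sites):
            j = site_levels.index(s)
            if j > 0:
                Z[i, j - 1] = 1.0
        Zc = Z - Z.mean(axis=0)
        g = 1 + (len(site_levels) - 1)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    def _ezekiel(r2, n_, p_):
        return 1.0 - (1.0 - r2) * (n_ - 1) / (n_ - p_ - 1)

    records = []
    for j in range(k):
        Y = dev[:, j, :]
        ss_tot = float(np.sum(Y**2))
        if Zc is not None and ss_tot > 0:
            beta, *_ = np.linalg.lstsq(Zc, Y, rcond=None)
            Yr = Y - Zc @ beta
            r2_z = float(np.sum((Zc @ beta) ** 2)) / ss_tot
        else:
            Yr = Y
            r2_z = 0.0
        mean_r = Yr.mean(axis=0)
        if ss_tot > 0:
            r2_xz = r2_z + n * float(np.sum(mean_r**2)) / ss_tot
        else:
            r2_xz = 0.0
        r2_adj = _ezekiel(r2_xz, n, g) - (_ezekiel(r2_z, n, g - 1) if g > 1 else 0.0)
        obs = float(np.sum(mean_r**2))
        perm_means = (signs @ Yr) / n  # n_perm x d
        perm_stat = np.sum(perm_means**2, axis=1)
        p = (int(np.sum(perm_stat >= obs - 1e-18)) + 1) / (n_perm + 1)
        records.append({"landmark": j + 1, "R2_adj": r2_adj, "P": p})
    out = pd.DataFrame(records)
    out["P_adj"] = multipletests(out["P"].to_numpy(), method="fdr_bh")[1]
    return out
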
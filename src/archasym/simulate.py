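"""Synthetic bilateral landmark data with known variance structure.

The generator emulates the study design this package analyses: paired
crescent-shaped pharyngeal arches digitised twice per side, with

* among-individual shape variation (``sigma_ind``),
* a directional left-right offset (``da_vector``, optionally coupled to
  the dental formula),
* individual x side fluctuating-asymmetry variation (``sigma_fa``),
* digitising (measurement) error per replicate session (``sigma_me``),
* per-site mean-shape displacements, and
* site-dependent binary dental-formula frequencies.

All deviations are isotropic Gaussian per landmark coordinate, applied in
shape space *before* superimposition, so the analysis pipeline must
recover them through GPA exactly as with real data.  The mean template
has unit centroid size, making the sigmas directly interpretable as
fractions of configuration size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import Configuration, ConfigurationSet, LandmarkScheme, default_scheme

__all__ = [
    "SimulationParams",
    "mean_arch_shape",
    "default_da_vector",
    "simulate_shapes",
    "simulate_formulae",
    "study_mimic_dataset",
]

#: default crescent template parameters
DEFAULT_BASE_SHAPE = {
    "outer_radius": 1.0,
    "radius_decay": 0.75,
    "arc_span": 1.9,       # radians, half-span of the outer curve
    "tip_radius": 1.15,
    "z_amplitude": 0.15,
    "unit_size": True,
}

BASAL_FORMULA = "1,5–5,1"
ALTERNATIVE_FORMULA = "1,5–4,1"


def mean_arch_shape(
    scheme: LandmarkScheme | None = None, base_shape: dict | None = None
) -> Configuration:
    """Deterministic crescent-shaped mean configuration for a scheme.

    Semi-landmark chains become smooth 3D arcs (outer and inner curves of
    the arch); fixed landmarks not anchoring a chain are placed at the
    structure's tips.  With ``unit_size`` (default) the configuration is
    centered and scaled to centroid size 1.
    """
    scheme = scheme or default_scheme()
    params = dict(DEFAULT_BASE_SHAPE)
    if base_shape:
        params.update(base_shape)
    span = float(params["arc_span"])
    if span <= 1e-6:
        raise ValueError("degenerate base shape: arc_span must be positive")
    if params["outer_radius"] <= 0:
        raise ValueError("degenerate base shape: outer_radius must be positive")

    coords = np.full((scheme.n_points, 3), np.nan)
    placed: set[int] = set()
    for ci, chain in enumerate(scheme.chains):
        path = [chain.start] + list(chain.semis) + [chain.end]
        radius = params["outer_radius"] * params["radius_decay"] ** ci
        chain_span = span * 0.95**ci
        angles = np.linspace(-chain_span, chain_span, len(path))
        z = params["z_amplitude"] * (-1.0) ** ci * np.sin(angles) + 0.1 * ci
        for p, a, zz in zip(path, angles, z):
            coords[p - 1] = [radius * np.cos(a), radius * np.sin(a), zz]
            placed.add(p)
    leftover = [i for i in scheme.fixed if i not in placed]
    for j, p in enumerate(leftover):
        ang = (span + 0.35 + 0.22 * (j // 2)) * (-1.0 if j % 2 == 0 else 1.0)
        coords[p - 1] = [
            params["tip_radius"] * np.cos(ang),
            params["tip_radius"] * np.sin(ang),
            0.12 * (j + 1),
        ]
    if np.any(np.isnan(coords)):
        raise ValueError("scheme points not covered by the template construction")
    if scheme.dims == 2:
        coords = coords[:, :2]
    coords -= coords.mean(axis=0)
    if params["unit_size"]:
        size = np.sqrt(np.sum(coords**2))
        if size < 1e-12:
            raise ValueError("degenerate base shape: zero centroid size")
        coords /= size
    return Configuration(coords=coords, individual="template", side="L")


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the similarity-transform directions at a
    centered template: translations, infinitesimal rotations and scaling."""
    k, d = template.shape
    dirs = []
    for j in range(d):
        e = np.zeros((k, d))
        e[:, j] = 1.0
        dirs.append(e.ravel())
    if d == 2:
        gens = [np.array([[0.0, -1.0], [1.0, 0.0]])]
    else:
        gens = [
            np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
            np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]], dtype=float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
        ]
    for A in gens:
        dirs.append((template @ A.T).ravel())
    dirs.append(template.ravel())  # scaling
    Q, _ = np.linalg.qr(np.array(dirs).T)
    return Q.T


def default_da_vector(scheme: LandmarkScheme | None = None, magnitude: float = 0.008) -> np.ndarray:
    """Directional-asymmetry offset: a z-displacement at the inner-curve
    semi-landmarks, projected into shape space.

    The raw displacement pattern is projected into the subspace where a
    directional offset is identifiable: orthogonal to the similarity
    transforms of the template (translation, rotation, scaling, which
    superimposition removes) and to the curve-tangent directions at the
    semi-landmarks (whose along-curve positions sliding treats as
    arbitrary).  The result is rescaled so its Frobenius norm equals
    ``magnitude * sqrt(#displaced landmarks)``.
    """
    scheme = scheme or default_scheme()
    da = np.zeros((scheme.n_points, scheme.dims))
    if scheme.chains:
        target = scheme.chains[-1].semis
    else:
        target = tuple(range(1, scheme.n_points + 1))
    for p in target:
        da[p - 1, -1] = magnitude
    template = mean_arch_shape(scheme).coords
    from .procrustes import _chain_tangents

    nuisance = list(_similarity_basis(template))
    s_idx, U = _chain_tangents(template, scheme)
    for j, u in zip(s_idx, U):
        e = np.zeros_like(template)
        e[j] = u
        nuisance.append(e.ravel())
    Q, _ = np.linalg.qr(np.array(nuisance).T)
    basis = Q.T
    flat = da.ravel() - basis.T @ (basis @ da.ravel())
    flat *= magnitude * np.sqrt(len(target)) / np.linalg.norm(flat)
    return flat.reshape(scheme.n_points, scheme.dims)


@dataclass
class SimulationParams:
    """Everything that defines one synthetic bilateral dataset.

    Default noise magnitudes are fractions of the (unit) template
    centroid size; they were fixed once so that directional- and
    fluctuating-asymmetry tests at 35 individuals have high (~0.8+)
    power, mimicking the effect sizes the analysis is meant to detect.
    """

    scheme: LandmarkScheme = field(default_factory=default_scheme)
    base_shape: dict | None = None
    sigma_ind: float = 0.010
    da_vector: np.ndarray | None = None
    sigma_fa: float = 0.004
    sigma_me: float = 0.002
    site_effects: dict[str, np.ndarray] | None = None
    formula_model: dict[str, float] | None = None
    coupling: bool = False
    n_per_site: dict[str, int] = field(default_factory=lambda: {"S1": 20})
    n_replicates: int = 2
    seed: int = 0
    biotype: str = "hybrid"
    lineage: str = "B-01"

    def __post_init__(self) -> None:
        for name in ("sigma_ind", "sigma_fa", "sigma_me"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.formula_model:
            for site, p in self.formula_model.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"formula probability for {site} outside [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _formula_rng(params: SimulationParams) -> np.ndarray:
    return np.random.default_rng([params.seed, 11])


def _shape_rng(params: SimulationParams) -> np.ndarray:
    return np.random.default_rng([params.seed, 13])


def _draw_formulae(params: SimulationParams) -> list[dict]:
    """Per-individual Bernoulli formula draws (deterministic in the seed;
    shared between :func:`simulate_formulae` and :func:`simulate_shapes`)."""
    rng = _formula_rng(params)
    records = []
    for site in sorted(params.n_per_site):
        n = params.n_per_site[site]
        if params.formula_model is not None:
            if site not in params.formula_model:
                raise ValueError(f"no formula probability for site {site!r}")
            p_alt = params.formula_model[site]
        else:
            p_alt = 0.0
        draws = rng.random(n) < p_alt
        for i, alt in enumerate(draws):
            records.append(
                {
                    "individual": f"{site}-{i + 1:03d}",
                    "site": site,
                    "lineage": params.lineage,
                    "biotype": params.biotype,
                    "formula": ALTERNATIVE_FORMULA if alt else BASAL_FORMULA,
                }
            )
    return records


def simulate_formulae(params: SimulationParams) -> list[dict]:
    """Per-individual dental-formula records with site-specific
    alternative-formula probabilities."""
    return _draw_formulae(params)


def simulate_shapes(params: SimulationParams) -> ConfigurationSet:
    """Generate the full bilateral configuration set.

    Per individual: shape = template + site effect + individual deviation.
    The left side additionally receives the directional offset (for every
    individual, or only alternative-formula ones when ``coupling``) and
    its own fluctuating deviation; the right side is the mirrored shape
    (x negated) with an independent fluctuating deviation.  Every
    digitising replicate adds independent measurement noise.
    """
    scheme = params.scheme
    template = mean_arch_shape(scheme, params.base_shape).coords
    k, d = template.shape
    da = params.da_vector
    if da is not None:
        da = np.asarray(da, dtype=float)
        if da.shape != (k, d):
            raise ValueError(f"da_vector must be {k} x {d}")
    rng = _shape_rng(params)
    records = _draw_formulae(params)
    configs: list[Configuration] = []
    for rec in records:
        site = rec["site"]
        site_eff = 0.0
        if params.site_effects is not None and site in params.site_effects:
            site_eff = np.asarray(params.site_effects[site], dtype=float)
        ind_dev = rng.normal(0.0, params.sigma_ind, size=(k, d)) if params.sigma_ind > 0 else 0.0
        shape = template + site_eff + ind_dev
        apply_da = da is not None and (
            not params.coupling or rec["formula"] == ALTERNATIVE_FORMULA
        )
        for side in ("L", "R"):
            fa = rng.normal(0.0, params.sigma_fa, size=(k, d)) if params.sigma_fa > 0 else 0.0
            if side == "L":
                side_shape = shape + (da if apply_da else 0.0) + fa
            else:
                mirrored = shape.copy()
                mirrored[:, 0] = -mirrored[:, 0]
                side_shape = mirrored + fa
            for rep in range(1, params.n_replicates + 1):
                me = (
                    rng.normal(0.0, params.sigma_me, size=(k, d))
                    if params.sigma_me > 0
                    else 0.0
                )
                configs.append(
                    Configuration(
                        coords=side_shape + me,
                        individual=rec["individual"],
                        side=side,
                        replicate=rep,
                        biotype=rec["biotype"],
                        lineage=rec["lineage"],
                        site=site,
                        formula=rec["formula"],
                    )
                )
    return ConfigurationSet(scheme, configs)


#: individuals per site for the study-design mimic (7 sites, 66 individuals)
MIMIC_SITE_SIZES = {"S1": 13, "S2": 12, "S3": 11, "S4": 9, "S5": 8, "S6": 7, "S7": 6}

#: site-specific probabilities of the alternative formula (spread like the
#: observed between-lake range, from rare to dominant)
MIMIC_FORMULA_PROBS = {"S1": 0.10, "S2": 0.25, "S3": 0.40, "S4": 0.50,
                       "S5": 0.60, "S6": 0.75, "S7": 0.90}


def study_mimic_dataset(seed: int = 0) -> tuple[ConfigurationSet, list[dict]]:
    """A dataset with the study's design dimensions: 66 individuals of one
    clonal lineage across 7 sites, 2 sides, 2 digitising sessions, 33
    landmarks; site mean-shape shifts and formula-coupled directional
    asymmetry.  Values are synthetic; only the design shape matches.
    """
    scheme = default_scheme()
    rng = np.random.default_rng([seed, 17])
    site_effects = {
        site: rng.normal(0.0, 0.006, size=(scheme.n_points, scheme.dims))
        for site in sorted(MIMIC_SITE_SIZES)
    }
    params = SimulationParams(
        scheme=scheme,
        da_vector=default_da_vector(scheme),
        site_effects=site_effects,
        formula_model=MIMIC_FORMULA_PROBS,
        coupling=True,
        n_per_site=dict(MIMIC_SITE_SIZES),
        n_replicates=2,
        seed=seed,
    )
    return simulate_shapes(params), simulate_formulae(params)
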
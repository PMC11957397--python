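"""Hierarchical Bayesian probabilistic matrix factorization engine.

The model places a low-rank factorization ``y_nm ~ N(<s_n, t_m>, sigma^2)``
on the observed entries of the log-abundance matrix at every hierarchy
level ``h``.  Sample latent vectors ``s_n^h`` form a Gaussian chain across
levels (``s_n^h ~ N(s_n^{h-1}, sigma_s^2 I)``, with ``s_n^0 = 0``), and
taxon latent vectors ``t_m^h`` take their parent cluster's latent vector
at the next-coarser level as prior mean (``t_m^h ~ N(t_{p(m)}^{h-1},
sigma_t^2 I)``, with ``T^0 = 0``).  Maximum a posteriori inference
minimizes, per level, the regularized squared loss

    E^h = sum_nm delta_nm (y_nm - <s_n, t_m>)^2
        + lambda_t sum_m [ ||t_m^h - t_{p(m)}^{h-1}||^2
                           + 1[h<H] sum_{m' in c(m)} ||t_m^h - t_{m'}^{h+1}||^2 ]
        + lambda_s sum_n [ ||s_n^h - s_n^{h-1}||^2
                           + 1[h<H] ||s_n^h - s_n^{h+1}||^2 ]

with ``lambda_t = sigma^2 / sigma_t^2`` and ``lambda_s = sigma^2 /
sigma_s^2``.  Posterior exploration uses a Gibbs sampler that sweeps the
levels top-down (coarsest to finest) and then bottom-up, drawing each
latent vector from its exact Gaussian full conditional; missing entries
are imputed by the posterior mean of ``<s_n^H, t_m^H>`` at the finest
level over the retained draws.

Levels are ordered coarsest first; the finest level (index ``H - 1``)
carries the matrix actually being imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .hierarchy import LEVELS, PhyloHierarchy, aggregate_matrix
from .preprocessing import CountMatrix, LogMatrix

__all__ = [
    "EngineConfig",
    "LevelData",
    "LevelMaps",
    "LatentState",
    "GibbsChain",
    "ImputationResult",
    "build_levels",
    "init_state",
    "conditional_update_t",
    "conditional_update_s",
    "gibbs_sweep",
    "run_chain",
    "impute",
    "objective",
    "impute_matrix",
]

_JITTER = 1e-10


@dataclass
class EngineConfig:
    """Sampler and prior settings.

    ``sigma2`` is the observation noise variance; ``sigma_s2``/``sigma_t2``
    are the prior variances of the sample/taxon latent chains (equivalently
    ridge weights ``lambda_s = sigma2/sigma_s2``, ``lambda_t =
    sigma2/sigma_t2``).  ``n_samples`` counts full Gibbs sweeps; the first
    ``burn_in`` are discarded and the rest thinned by ``thin``.
    """

    latent_dim: int = 10
    sigma2: float = 1.0
    sigma_s2: float = 1.0
    sigma_t2: float = 1.0
    n_samples: int = 200
    burn_in: int = 50
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if min(self.sigma2, self.sigma_s2, self.sigma_t2) <= 0:
            raise ValueError("variances must be positive")
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("need 0 <= burn_in < n_samples")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def lambda_s(self) -> float:
        return self.sigma2 / self.sigma_s2

    @property
    def lambda_t(self) -> float:
        return self.sigma2 / self.sigma_t2

    @property
    def n_retained(self) -> int:
        return (self.n_samples - self.burn_in) // self.thin


@dataclass
class LevelData:
    """Observed data at one hierarchy level: values and the delta mask
    (True where the entry is observed, False where missing)."""

    values: np.ndarray
    observed: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values/observed shape mismatch")


@dataclass
class LevelMaps:
    """Parent/child index maps between adjacent levels (coarsest first).

    ``parents[h][m]`` is the index of m's parent cluster at level ``h-1``
    (``parents[0]`` is None: the root prior mean is the zero vector);
    ``children[h][m]`` lists m's child indices at level ``h+1``
    (``children[H-1]`` is None).
    """

    parents: list[np.ndarray | None]
    children: list[list[np.ndarray] | None]

    @property
    def n_levels(self) -> int:
        return len(self.parents)


@dataclass
class LatentState:
    S_levels: list[np.ndarray]  # per level, N x D
    T_levels: list[np.ndarray]  # per level, M_h x D

    def copy(self) -> "LatentState":
        return LatentState(
            [s.copy() for s in self.S_levels], [t.copy() for t in self.T_levels]
        )


@dataclass
class GibbsChain:
    retained_states: list[LatentState]
    config: EngineConfig
    diagnostics: np.ndarray = field(default=None)  # type: ignore[assignment]
    # diagnostics: (n_samples, H) objective values E^h after each sweep


@dataclass
class ImputationResult:
    imputed: LogMatrix
    posterior_sd: np.ndarray  # NaN off the imputed entries
    n_draws_used: int


def build_levels(
    normalized: CountMatrix,
    flags: np.ndarray,
    hierarchy: PhyloHierarchy | None,
    offset: float,
    library_size: float = 1e6,
) -> tuple[list[LevelData], LevelMaps]:
    """Assemble per-level data matrices and parent/child maps.

    With a hierarchy the engine runs over four layers ordered coarsest to
    finest: F, G, S, then the individual taxa.  Without one it degrades to
    a single-level (plain PMF) model.
    """
    flags = np.asarray(flags, dtype=bool)
    finest_values = np.log10(np.where(flags, 0.0, normalized.values) + offset)
    finest = LevelData(finest_values, ~flags, list(normalized.taxon_ids))
    if hierarchy is None:
        return [finest], LevelMaps(parents=[None], children=[None])

    datas: list[LevelData] = []
    for lvl in reversed(LEVELS):  # F, G, S
        agg = aggregate_matrix(
            normalized, hierarchy, lvl, missing_mask=flags,
            offset=offset, library_size=library_size,
        )
        datas.append(LevelData(agg.values, ~agg.missing_mask, list(agg.taxon_ids)))
    datas.append(finest)

    parents: list[np.ndarray | None] = [None]
    # S-level parents of taxa come from the partition labels directly
    g_of_s = _parent_array(hierarchy, "S", "G")
    f_of_g = _parent_array(hierarchy, "G", "F")
    parents.append(f_of_g)  # G -> F
    parents.append(g_of_s)  # S -> G
    parents.append(hierarchy.labels("S"))  # taxa -> S
    children: list[list[np.ndarray] | None] = [
        _children_from_parents(parents[1], datas[0].values.shape[1]),
        _children_from_parents(parents[2], datas[1].values.shape[1]),
        _children_from_parents(parents[3], datas[2].values.shape[1]),
        None,
    ]
    return datas, LevelMaps(parents=parents, children=children)


def _parent_array(h: PhyloHierarchy, fine: str, coarse: str) -> np.ndarray:
    n = h.n_clusters(fine)
    return np.array([h.parent[(fine, c)] for c in range(n)], dtype=int)


def _children_from_parents(parents: np.ndarray, n_parents: int) -> list[np.ndarray]:
    return [np.flatnonzero(parents == c) for c in range(n_parents)]


def init_state(
    config: EngineConfig,
    data_levels: list[LevelData],
    rng: np.random.Generator | None = None,
) -> LatentState:
    """Draw all latent vectors i.i.d. from their root priors."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    D = config.latent_dim
    S_levels, T_levels = [], []
    for lvl in data_levels:
        n, m = lvl.values.shape
        S_levels.append(rng.normal(0.0, np.sqrt(config.sigma_s2), size=(n, D)))
        T_levels.append(rng.normal(0.0, np.sqrt(config.sigma_t2), size=(m, D)))
    return LatentState(S_levels, T_levels)


def _sample_gaussian(
    precision: np.ndarray, b: np.ndarray, rng: np.random.Generator | None
) -> np.ndarray:
    """Draw from N(precision^-1 b, precision^-1); rng=None returns the mean."""
    try:
        c, low = cho_factor(precision, lower=False)
    except np.linalg.LinAlgError:
        precision = precision + _JITTER * np.eye(precision.shape[0])
        c, low = cho_factor(precision, lower=False)
    mean = cho_solve((c, low), b)
    if rng is None:
        return mean
    z = rng.standard_normal(b.shape[0])
    # upper-triangular R with R'R = precision: x = mean + R^-1 z
    from scipy.linalg import solve_triangular

    return mean + solve_triangular(c, z, lower=False)


def conditional_update_t(
    m: int,
    h: int,
    state: LatentState,
    data_levels: list[LevelData],
    maps: LevelMaps,
    config: EngineConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Sample t_m^h from its Gaussian full conditional.

    Precision: (1/sigma2) sum_n delta s s' + (1/sigma_t2)(1 + |c(m)| 1[h<H]) I;
    mean solves precision @ mu = (1/sigma2) sum_n delta y s
    + (1/sigma_t2)(t_parent + sum_children t).  ``rng=None`` returns the
    conditional mean instead of a draw.
    """
    lvl = data_levels[h]
    D = config.latent_dim
    rows = np.flatnonzero(lvl.observed[:, m])
    S = state.S_levels[h][rows]
    prior_vec = np.zeros(D)
    n_links = 1.0  # own prior (parent is T^0 = 0 at the root)
    if maps.parents[h] is not None:
        prior_vec += state.T_levels[h - 1][maps.parents[h][m]]
    if maps.children[h] is not None:
        kids = maps.children[h][m]
        n_links += len(kids)
        if len(kids):
            prior_vec = prior_vec + state.T_levels[h + 1][kids].sum(axis=0)
    precision = (S.T @ S) / config.sigma2 + (n_links / config.sigma_t2) * np.eye(D)
    b = (S.T @ lvl.values[rows, m]) / config.sigma2 + prior_vec / config.sigma_t2
    return _sample_gaussian(precision, b, rng)


def conditional_update_s(
    n: int,
    h: int,
    state: LatentState,
    data_levels: list[LevelData],
    maps: LevelMaps,
    config: EngineConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Sample s_n^h from its Gaussian full conditional (chain prior:
    parent s_n^{h-1} with S^0 = 0, plus the single child s_n^{h+1} when
    h < H)."""
    lvl = data_levels[h]
    D = config.latent_dim
    cols = np.flatnonzero(lvl.observed[n, :])
    T = state.T_levels[h][cols]
    prior_vec = np.zeros(D)
    n_links = 1.0
    if h > 0:
        prior_vec += state.S_levels[h - 1][n]
    if h < len(data_levels) - 1:
        n_links += 1.0
        prior_vec = prior_vec + state.S_levels[h + 1][n]
    precision = (T.T @ T) / config.sigma2 + (n_links / config.sigma_s2) * np.eye(D)
    b = (T.T @ lvl.values[n, cols]) / config.sigma2 + prior_vec / config.sigma_s2
    return _sample_gaussian(precision, b, rng)


def _update_level(state, h, data_levels, maps, config, rng) -> None:
    for m in range(state.T_levels[h].shape[0]):
        state.T_levels[h][m] = conditional_update_t(
            m, h, state, data_levels, maps, config, rng
        )
    for n in range(state.S_levels[h].shape[0]):
        state.S_levels[h][n] = conditional_update_s(
            n, h, state, data_levels, maps, config, rng
        )


def gibbs_sweep(
    state: LatentState,
    data_levels: list[LevelData],
    maps: LevelMaps,
    config: EngineConfig,
    rng: np.random.Generator,
) -> LatentState:
    """One full sweep: levels coarsest-to-finest then finest-to-coarsest,
    updating all taxon vectors then all sample vectors per level, in place
    and sequentially (each draw conditions on the newest values)."""
    H = len(data_levels)
    for h in range(H):
        _update_level(state, h, data_levels, maps, config, rng)
    for h in range(H - 2, -1, -1):
        _update_level(state, h, data_levels, maps, config, rng)
    return state


def run_chain(
    data_levels: list[LevelData],
    maps: LevelMaps,
    config: EngineConfig,
) -> GibbsChain:
    """Run the Gibbs sampler and retain post-burn-in, thinned states."""
    rng = np.random.default_rng(config.seed)
    state = init_state(config, data_levels, rng)
    retained: list[LatentState] = []
    diags = np.zeros((config.n_samples, len(data_levels)))
    for i in range(1, config.n_samples + 1):
        gibbs_sweep(state, data_levels, maps, config, rng)
        diags[i - 1] = objective(state, data_levels, maps, config)
        if i > config.burn_in and (i - config.burn_in) % config.thin == 0:
            retained.append(state.copy())
    return GibbsChain(retained_states=retained, config=config, diagnostics=diags)


def impute(
    chain: GibbsChain,
    flagged_mask: np.ndarray,
    finest_matrix: LogMatrix,
) -> ImputationResult:
    """Posterior-mean imputation of flagged entries at the finest level.

    Each flagged entry (n, m) gets the mean over retained draws of
    ``<s_n^H, t_m^H>``, clamped below at log10(offset) so back-transformed
    counts are never negative; all other entries are untouched.
    """
    if not chain.retained_states:
        raise ValueError("empty chain: no retained draws")
    flagged_mask = np.asarray(flagged_mask, dtype=bool)
    rows, cols = np.nonzero(flagged_mask)
    draws = np.empty((len(chain.retained_states), len(rows)))
    for k, st in enumerate(chain.retained_states):
        S, T = st.S_levels[-1], st.T_levels[-1]
        draws[k] = np.einsum("ij,ij->i", S[rows], T[cols])
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1) if draws.shape[0] > 1 else np.zeros(len(rows))
    floor = finest_matrix.zero_value
    out = finest_matrix.copy()
    out.values[rows, cols] = np.maximum(mean, floor)
    out.missing_mask[rows, cols] = False
    sd_full = np.full(flagged_mask.shape, np.nan)
    sd_full[rows, cols] = sd
    return ImputationResult(
        imputed=out, posterior_sd=sd_full, n_draws_used=len(chain.retained_states)
    )


def objective(
    state: LatentState,
    data_levels: list[LevelData],
    maps: LevelMaps,
    config: EngineConfig,
) -> np.ndarray:
    """Per-level regularized squared loss E^h (see module docstring)."""
    H = len(data_levels)
    out = np.zeros(H)
    for h in range(H):
        lvl = data_levels[h]
        S, T = state.S_levels[h], state.T_levels[h]
        resid = lvl.values - S @ T.T
        e = float(np.sum(resid[lvl.observed] ** 2))
        # taxon-side penalties
        if maps.parents[h] is None:
            e += config.lambda_t * float(np.sum(T**2))
        else:
            Tp = state.T_levels[h - 1][maps.parents[h]]
            e += config.lambda_t * float(np.sum((T - Tp) ** 2))
        if maps.children[h] is not None:
            Tnext = state.T_levels[h + 1]
            for m, kids in enumerate(maps.children[h]):
                if len(kids):
                    e += config.lambda_t * float(np.sum((T[m] - Tnext[kids]) ** 2))
        # sample-side penalties
        Sprev = state.S_levels[h - 1] if h > 0 else np.zeros_like(S)
        e += config.lambda_s * float(np.sum((S - Sprev) ** 2))
        if h < H - 1:
            e += config.lambda_s * float(np.sum((S - state.S_levels[h + 1]) ** 2))
        out[h] = e
    return out


def impute_matrix(
    normalized: CountMatrix,
    flags: np.ndarray,
    hierarchy: PhyloHierarchy | None,
    config: EngineConfig,
    offset: float = 1.01,
    library_size: float = 1e6,
) -> ImputationResult:
    """Convenience wrapper: build level data, run the chain, impute."""
    data_levels, maps = build_levels(
        normalized, flags, hierarchy, offset, library_size
    )
    chain = run_chain(data_levels, maps, config)
    finest = LogMatrix(
        data_levels[-1].values,
        list(normalized.sample_ids),
        list(normalized.taxon_ids),
        offset=offset,
        library_size=library_size,
        missing_mask=np.asarray(flags, dtype=bool),
    )
    return impute(chain, flags, finest)
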
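"""Random profile generation with real-profile properties.

Random profiles are produced by concatenating fixed-length fragments
sampled from a pool of noisy MSAs that were themselves generated from seed
profiles.  Two parameters control the degree of similarity among the
resulting profiles: the fragment length s (larger s preserves more of the
local column dependencies of the seeds, increasing correlation between
random profiles) and the noise level r (the per-residue probability of
replacing a sampled residue with a background draw, decorrelating
profiles).  The defaults s=9 and r=0.03 are the settings at which the
simulated alignment-score distributions best balance extreme-value
goodness of fit against closeness to reference score distributions.

Because no external data are required, seed profiles are synthesized from
a column process with short-range correlation (an AR(1) mixture of
Dirichlet draws around the background composition), smoothed runs of
secondary-structure states, and transition probabilities near values
typical of real protein families.  Any real profile can be substituted as
a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import BACKGROUND, N_AA
from .errors import GenerationError, InputError
from .msa import Msa, compute_eno
from .profile import Profile, build_profile_from_msa

__all__ = [
    "SimulationConfig",
    "GridSpec",
    "FragmentPool",
    "make_synthetic_seed",
    "generate_noisy_msa",
    "sample_fragment_pool",
    "generate_random_profile",
    "generate_profile_grid",
    "make_source_msas",
    "default_seeds",
]

DEFAULT_LENGTHS = (50, 100, 200, 400, 600, 800)
DEFAULT_ENOS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)


@dataclass
class SimulationConfig:
    """Parameters of the random-profile generator.

    s and r default to the calibrated optimum (s=9, r=0.03).  S seed
    profiles each give rise to M noisy source MSAs; fragments are drawn
    from the pooled MSAs.
    """

    s: int = 9
    r: float = 0.03
    S: int = 96
    M: int = 16
    rng_seed: int = 0
    seed_length: int = 160
    seed_concentration: float = 5.0
    msa_kappa: float = 30.0
    msa_depth: int = 64
    pool_size: int = 4000

    def __post_init__(self) -> None:
        if self.s < 1 or self.S < 1 or self.M < 1:
            raise InputError("s, S and M must be positive")
        if not (0 <= self.r <= 1):
            raise InputError("r must be in [0, 1]")


@dataclass
class GridSpec:
    """Calibration grid: profile lengths L, ENOs N and the width of the
    compositional-similarity bins."""

    lengths: tuple = DEFAULT_LENGTHS
    enos: tuple = DEFAULT_ENOS
    lambda_bin: float = 0.1

    def cells(self) -> list[tuple[int, float]]:
        return [(l, n) for l in self.lengths for n in self.enos]


@dataclass
class FragmentPool:
    """Fixed-length MSA blocks (all rows retained) tagged with the index of
    the source MSA they were cut from.

    When fragments were drawn exclusively (mutually non-overlapping
    windows), consuming them via :meth:`take` guarantees that no window is
    shared between the profiles assembled from one pool.
    """

    fragments: list = field(default_factory=list)  # list of (depth, s) code arrays
    source_ids: list = field(default_factory=list)
    #: per-fragment (s, 3) SS-state probabilities carried along from the
    #: source MSA's annotation (never inspected during sampling)
    ss_blocks: list = field(default_factory=list)
    s: int = 0
    exclusive: bool = False
    _cursor: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        for frag in self.fragments:
            if frag.shape[1] != self.s:
                raise InputError("every fragment must have exactly s columns")

    @property
    def remaining(self) -> int:
        return len(self.fragments) - self._cursor

    def take(self, k: int) -> list[int]:
        """Consume the next k fragment indices (draw order is random)."""
        if self.remaining < k:
            raise GenerationError(
                f"fragment pool exhausted: {k} requested, {self.remaining} left"
            )
        out = list(range(self._cursor, self._cursor + k))
        self._cursor += k
        return out


def _dirichlet_columns(length: int, concentration: float, rho: float,
                       rng: np.random.Generator) -> np.ndarray:
    alpha = concentration * N_AA * BACKGROUND
    raw = rng.dirichlet(alpha, size=length)
    cols = np.empty_like(raw)
    cols[0] = raw[0]
    for i in range(1, length):
        cols[i] = rho * cols[i - 1] + (1 - rho) * raw[i]
    cols /= cols.sum(axis=1, keepdims=True)
    return cols


def _synthetic_ss(length: int, rng: np.random.Generator,
                  stay: float = 0.9, peak: float = 0.75) -> np.ndarray:
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.integers(3)
    for i in range(1, length):
        if rng.random() < stay:
            states[i] = states[i - 1]
        else:
            states[i] = (states[i - 1] + 1 + rng.integers(2)) % 3
    probs = np.full((length, 3), (1 - peak) / 2)
    probs[np.arange(length), states] = peak
    # light smoothing across neighbours keeps state runs realistic
    kernel = np.array([0.2, 0.6, 0.2])
    padded = np.vstack([probs[:1], probs, probs[-1:]])
    smooth = (kernel[0] * padded[:-2] + kernel[1] * padded[1:-1]
              + kernel[2] * padded[2:])
    smooth /= smooth.sum(axis=1, keepdims=True)
    return smooth


def make_synthetic_seed(length: int, target_eno: float = 10.0,
                        concentration: float = 3.0,
                        rng: np.random.Generator | None = None,
                        id: str = "seed") -> Profile:
    """Synthesize a seed profile with real-profile-like structure.

    Columns follow an AR(1)-correlated Dirichlet process centred on the
    background; SS-state probabilities form smoothed runs of H/E/C;
    transition probabilities are drawn near typical values.  Larger
    ``concentration`` pulls all columns toward the background composition.
    """
    if length < 1 or target_eno < 1:
        raise InputError("length and target_eno must be >= 1")
    rng = rng or np.random.default_rng()
    target = _dirichlet_columns(length, concentration, rho=0.5, rng=rng)
    ss = _synthetic_ss(length, rng)
    mi = np.clip(rng.beta(2.0, 48.0, size=length), 1e-4, 0.4)
    md = np.clip(rng.beta(2.0, 48.0, size=length), 1e-4, 0.4)
    mm = 1.0 - mi - md
    ii = np.clip(rng.beta(8.0, 12.0, size=length), 1e-3, 0.95)
    dd = np.clip(rng.beta(8.0, 12.0, size=length), 1e-3, 0.95)
    trans = np.column_stack([mm, mi, md, ii, 1 - ii, dd, 1 - dd])
    with np.errstate(divide="ignore"):
        ent = -np.sum(np.where(target > 0, target * np.log(target), 0.0), axis=1)
    return Profile(
        id=id,
        target_probs=target,
        log_odds=np.log(target / BACKGROUND[None, :]),
        trans_probs=trans,
        eff_counts=np.maximum(np.exp(ent), 1.0),
        eno=float(target_eno),
        background_probs=BACKGROUND.copy(),
        ss_probs=ss,
    )


def generate_noisy_msa(seed: Profile, n_sequences: int, r: float,
                       rng: np.random.Generator | None = None) -> Msa:
    """Sample an MSA from a seed profile with per-residue background noise.

    Each sequence is drawn column-wise from the seed's target
    probabilities; every sampled residue is then independently replaced
    with probability ``r`` by a draw from the background.  Deletion states
    follow the seed's M->D / D->D transitions and appear as gap columns;
    insert states are not emitted since rows are kept rectangular on the
    seed's match columns.
    """
    if n_sequences < 1:
        raise InputError("n_sequences must be >= 1")
    if not (0 <= r <= 1):
        raise InputError("r must be in [0, 1]")
    rng = rng or np.random.default_rng()
    L = seed.length
    n = n_sequences
    cum = np.cumsum(seed.target_probs, axis=1)
    cum[:, -1] = 1.0
    codes = np.empty((n, L), dtype=np.int8)
    u = rng.random((n, L))
    for i in range(L):
        codes[:, i] = np.searchsorted(cum[i], u[:, i], side="right")
    if r > 0:
        noise_mask = rng.random((n, L)) < r
        n_noise = int(noise_mask.sum())
        if n_noise:
            repl = np.searchsorted(np.cumsum(BACKGROUND), rng.random(n_noise),
                                   side="right").astype(np.int8)
            codes[noise_mask] = repl
    # deletion chain along columns
    deleted = np.zeros(n, dtype=bool)
    for i in range(L):
        p_open = seed.trans_probs[i, 2]
        p_stay = seed.trans_probs[i, 5]
        u2 = rng.random(n)
        deleted = np.where(deleted, u2 < p_stay, u2 < p_open)
        codes[deleted, i] = 20
    msa = Msa.from_codes(codes)
    if seed.ss_probs is not None:
        # the SS annotation is a stand-in for an SS prediction computed
        # from the noisy MSA: noise perturbs it position-wise as well
        ss = seed.ss_probs.copy()
        flip = np.nonzero(rng.random(L) < r)[0]
        if flip.size:
            states = rng.integers(3, size=flip.size)
            repl = np.full((flip.size, 3), 0.125)
            repl[np.arange(flip.size), states] = 0.75
            ss[flip] = repl
        msa.ss_probs = ss
    return msa


def sample_fragment_pool(msas: list[Msa], s: int, pool_size: int = 2000,
                         rng: np.random.Generator | None = None,
                         exclusive: bool = True) -> FragmentPool:
    """Sample ``pool_size`` contiguous s-column windows, with uniformly
    random source MSA and start position.  Fragment content (including any
    SS signal it implies) is never inspected.

    With ``exclusive=True`` (default) windows are drawn without overlap:
    a drawn window blocks the surrounding positions of its source MSA, so
    no two pool fragments share any MSA column.  This keeps the fragment
    draws collision-free, as they effectively are when the window universe
    is very large (many seed profiles), at the modest pool sizes used here.
    """
    rng = rng or np.random.default_rng()
    eligible = [(idx, m) for idx, m in enumerate(msas) if m.length >= s]
    if not eligible:
        raise InputError(f"no MSA has length >= s={s}")
    fragments: list[np.ndarray] = []
    source_ids: list[int] = []
    ss_blocks: list = []
    taken: dict[int, list[tuple[int, int]]] = {}
    misses = 0
    max_misses = 50 * pool_size
    while len(fragments) < pool_size:
        k = int(rng.integers(len(eligible)))
        idx, m = eligible[k]
        start = int(rng.integers(m.length - s + 1))
        if exclusive:
            spans = taken.setdefault(idx, [])
            if any(start < b and start + s > a for a, b in spans):
                misses += 1
                if misses > max_misses:
                    raise InputError(
                        "cannot draw enough non-overlapping fragments; "
                        "increase the number of source MSAs or reduce pool_size"
                    )
                continue
            spans.append((start, start + s))
        fragments.append(m.codes()[:, start:start + s].copy())
        source_ids.append(idx)
        ss_blocks.append(None if m.ss_probs is None
                         else m.ss_probs[start:start + s].copy())
    return FragmentPool(fragments=fragments, source_ids=source_ids,
                        ss_blocks=ss_blocks, s=s, exclusive=exclusive)


def _assemble_codes(pool: FragmentPool, length: int,
                    rng: np.random.Generator, consume: bool):
    k = math.ceil(length / pool.s)
    if consume:
        picks = pool.take(k)
    else:
        picks = [int(i) for i in rng.integers(len(pool.fragments), size=k)]
    frags = [pool.fragments[i] for i in picks]
    depth = min(f.shape[0] for f in frags)
    rows = []
    for f in frags:
        if f.shape[0] > depth:
            sel = rng.choice(f.shape[0], size=depth, replace=False)
            f = f[sel]
        rows.append(f)
    blocks = [pool.ss_blocks[i] for i in picks] if pool.ss_blocks else []
    if blocks and all(b is not None for b in blocks):
        ss = np.vstack(blocks)[:length]
    else:
        ss = None
    return np.hstack(rows)[:, :length], ss


def generate_random_profile(pool: FragmentPool, length: int, target_eno: float,
                            rng: np.random.Generator | None = None,
                            eno_tol: float = 0.5, max_retries: int = 20,
                            pseudocount_strength: float = 2.0,
                            id: str | None = None,
                            consume: bool = False) -> Profile:
    """Assemble a random profile of the requested length and ENO.

    ceil(length/s) fragments are drawn (with replacement from the pool, or
    consumed without reuse when ``consume=True``) and concatenated
    row-wise (row i of one fragment continues as row i of the next), then
    truncated to ``length`` columns.  The number of retained rows is
    adjusted by bisection until the assembled MSA's ENO falls within
    ``eno_tol`` of the target.  The profile inherits the concatenated
    SS-state annotation the fragments carry; fragment selection never
    inspects it.
    """
    if not pool.fragments:
        raise InputError("fragment pool is empty")
    if length < 1:
        raise InputError("length must be >= 1")
    rng = rng or np.random.default_rng()
    last_eno = None
    for attempt in range(max_retries):
        codes, ss = _assemble_codes(pool, length, rng, consume)
        depth = codes.shape[0]
        order = rng.permutation(depth)
        lo, hi = 1, depth
        best = None
        for _ in range(int(math.ceil(math.log2(depth))) + 2):
            mid = (lo + hi + 1) // 2
            sub = codes[order[:mid]]
            msa = Msa.from_codes(sub)
            eno = compute_eno(msa)
            if best is None or abs(eno - target_eno) < abs(best[1] - target_eno):
                best = (msa, eno)
            if abs(eno - target_eno) <= eno_tol:
                break
            if eno > target_eno:
                hi = max(mid - 1, 1)
            else:
                lo = min(mid + 1, depth)
            if lo >= hi:
                sub = codes[order[:lo]]
                msa = Msa.from_codes(sub)
                eno = compute_eno(msa)
                if abs(eno - target_eno) < abs(best[1] - target_eno):
                    best = (msa, eno)
                break
        msa, eno = best
        last_eno = eno
        if abs(eno - target_eno) <= eno_tol:
            profile = build_profile_from_msa(
                msa, pseudocount_strength=pseudocount_strength,
                id=id or f"rand_l{length}_n{target_eno:g}",
            )
            profile.ss_probs = ss if ss is not None else _synthetic_ss(length, rng)
            return profile
    raise GenerationError(
        f"could not reach ENO {target_eno} +/- {eno_tol} for length {length}; "
        f"closest achieved {last_eno:.2f}"
    )


def _jittered_copy(seed: Profile, kappa: float, rng: np.random.Generator) -> Profile:
    """Per-MSA profile model: each source MSA samples from a Dirichlet-
    perturbed copy of its seed (concentration kappa around the seed's
    columns), so that two MSAs covering the same seed region are similar
    but not deterministic replicas of each other."""
    import copy as _copy

    jit = _copy.copy(seed)
    jit.target_probs = np.stack(
        [rng.dirichlet(kappa * p + 0.02) for p in seed.target_probs]
    )
    return jit


def make_source_msas(seeds: list[Profile], cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[Msa]:
    """The S x M noisy source MSAs of the generation algorithm."""
    out = []
    for seed in seeds:
        for _ in range(cfg.M):
            model = (_jittered_copy(seed, cfg.msa_kappa, rng)
                     if cfg.msa_kappa and cfg.msa_kappa > 0 else seed)
            out.append(generate_noisy_msa(model, cfg.msa_depth, cfg.r, rng))
    return out


def generate_profile_grid(seeds: list[Profile], grid: GridSpec, per_cell: int,
                          cfg: SimulationConfig) -> dict[tuple[int, float], list[Profile]]:
    """Generate ``per_cell`` random profiles for every (length, ENO) cell.

    Deterministic for a fixed ``cfg.rng_seed``.
    """
    if per_cell < 2:
        raise InputError("per_cell must be >= 2")
    rng = np.random.default_rng(cfg.rng_seed)
    msas = make_source_msas(seeds, cfg, rng)
    # consume fragments without cross-profile reuse: size the pool to the
    # demand (with retry headroom) so no window is shared between profiles
    need = int(1.5 * per_cell * sum(math.ceil(l / cfg.s) for l, _ in grid.cells()))
    pool = sample_fragment_pool(msas, cfg.s, need, rng)
    out: dict[tuple[int, float], list[Profile]] = {}
    for (l, n) in grid.cells():
        profiles = []
        for j in range(per_cell):
            try:
                profiles.append(
                    generate_random_profile(
                        pool, l, n, rng, id=f"rand_l{l}_n{n:g}_{j}",
                        consume=True,
                    )
                )
            except GenerationError as exc:
                raise GenerationError(f"cell (l={l}, n={n}): {exc}") from exc
        out[(l, n)] = profiles
    return out


def default_seeds(cfg: SimulationConfig) -> list[Profile]:
    """Synthetic seed profiles for a simulation configuration."""
    rng = np.random.default_rng(cfg.rng_seed + 982451653 % (2**31))
    return [
        make_synthetic_seed(cfg.seed_length, target_eno=10.0,
                            concentration=cfg.seed_concentration,
                            rng=rng, id=f"seed{i}")
        for i in range(cfg.S)
    ]
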
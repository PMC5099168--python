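"""Odor stimulus generation and the odor pool.

An odorant is a vector of receptor affinities over the 100 sensory
channels: a fixed Gaussian profile (mean channel 50, width 10, peak
normalised to 1) randomly permuted across channels, so every odor delivers
the same total input to the sensory layer and differs only in *which*
channels it drives.

For experiments that need stimulus pairs at a controlled representation
distance, two mechanisms are provided:

* :func:`build_pool` / :func:`select_pair` -- the pool approach: simulate
  many random odors on a naive circuit, store each odor's pyramidal
  activation signature, and pick pairs by pairwise cosine distance.
* :func:`morph_odor` -- graded variants of a base odor made by exchanging a
  controlled fraction of rank-paired channels (strong channels swap their
  affinity with weak ones), which sweeps the input distance continuously
  from 0 towards ~1.  Random permutations alone cluster around distance
  ~0.65 and essentially never fall below ~0.4, so morphs are what makes the
  low-distance (recall) regime reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

__all__ = [
    "OdorPattern",
    "OdorPool",
    "gaussian_profile",
    "generate_odor",
    "morph_odor",
    "build_pool",
    "select_pair",
]

N_CHANNELS = 100
PROFILE_MU = 50.0
PROFILE_SIGMA = 10.0


@dataclass(frozen=True)
class OdorPattern:
    """Affinity of each sensory channel for this odorant, values in (0, 1]."""

    affinities: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.affinities, dtype=float)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("affinities must lie in [0, 1]")
        object.__setattr__(self, "affinities", a)

    @property
    def n(self) -> int:
        return self.affinities.size


def gaussian_profile(
    n: int = N_CHANNELS, mu: float = PROFILE_MU, sigma: float = PROFILE_SIGMA
) -> np.ndarray:
    """The fixed affinity profile: normal pdf over channels 1..n, divided by
    its peak so the maximum affinity is exactly 1."""
    x = np.arange(1, n + 1, dtype=float)
    pdf = norm.pdf(x, loc=mu, scale=sigma)
    return pdf / norm.pdf(mu, loc=mu, scale=sigma)


def generate_odor(
    seed: int | np.random.Generator, n: int = N_CHANNELS, id: str = ""
) -> OdorPattern:
    """A random odorant: the Gaussian profile under a seeded permutation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = gaussian_profile(n)
    return OdorPattern(affinities=rng.permutation(profile), id=id)


def morph_odor(
    base: OdorPattern,
    fraction: float,
    rng: int | np.random.Generator | None = None,
    id: str = "",
) -> OdorPattern:
    """A graded variant of ``base``: exchange the affinities of a fraction of
    rank-paired channels.

    Channels are sorted by affinity and channel of rank r is paired with
    rank r + n/2, so a full morph (fraction 1) moves every strong channel's
    affinity onto a formerly weak channel -- near-orthogonal to the base --
    while fraction 0 returns the base unchanged.  Which pairs swap is drawn
    from ``rng``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a = base.affinities.copy()
    n = a.size
    half = n // 2
    order = np.argsort(a, kind="stable")  # ascending: weak first
    n_swap = int(round(fraction * half))
    which = rng.choice(half, size=n_swap, replace=False)
    lo = order[which]            # weak channels
    hi = order[which + half]     # their strong partners
    a[lo], a[hi] = a[hi].copy(), a[lo].copy()
    return OdorPattern(affinities=a, id=id or f"{base.id}~morph{fraction:.2f}")


@dataclass
class OdorPool:
    """A pool of odors with stored pyramidal signatures and pairwise
    cosine distances between them."""

    odors: list[OdorPattern]
    pyr_signatures: np.ndarray  # (n_odors, n_pyr) mean activation vectors
    pairwise_d: np.ndarray      # (n_odors, n_odors), symmetric, zero diagonal

    def __len__(self) -> int:
        return len(self.odors)

    def to_csv(self, odor_path: str | Path, distance_path: str | Path | None = None) -> None:
        import pandas as pd

        rows = {o.id or str(i): o.affinities for i, o in enumerate(self.odors)}
        pd.DataFrame(rows).T.to_csv(odor_path, header=False)
        if distance_path is not None:
            pd.DataFrame(self.pairwise_d).to_csv(distance_path, index=False, header=False)


def build_pool(
    n: int,
    net,
    seed: int,
    signature_ms: float = 1000.0,
) -> OdorPool:
    """Generate ``n`` random odors and store each one's pyramidal signature.

    Each odor is presented for ``signature_ms`` to the *naive* network (state
    reset before each presentation, plasticity disabled, modulation at its
    spontaneous level) and the time-averaged pyramidal activity is stored.
    Pairwise signature distances use the cosine distance.
    """
    if n < 2:
        raise ValueError("pool needs at least two odors")
    rng = np.random.default_rng(seed)
    # signature runs draw from a dedicated stream so pool construction is
    # reproducible regardless of what the network simulated before
    net.reseed_run(int(np.random.SeedSequence([seed, 313]).generate_state(1)[0] % (2**31)))
    odors = [generate_odor(rng, id=f"odor{i:04d}") for i in range(n)]
    signatures = np.stack(
        [net.odor_signature(o, duration_ms=signature_ms, plastic=False) for o in odors]
    )
    # cosine distance; all-zero signatures (odor evokes nothing) map to
    # distance 1 from everything and 0 from themselves
    norms = np.linalg.norm(signatures, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = signatures / safe[:, None]
    d = 1.0 - unit @ unit.T
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return OdorPool(odors=odors, pyr_signatures=signatures, pairwise_d=d)


def select_pair(
    pool: OdorPool, target_d: float, tol: float
) -> tuple[OdorPattern, OdorPattern]:
    """The odor pair whose stored signature distance is closest to
    ``target_d`` within ``tol``; ties break to the smallest odor indices."""
    n = len(pool)
    iu = np.triu_indices(n, k=1)
    d = pool.pairwise_d[iu]
    err = np.abs(d - target_d)
    best = int(np.argmin(err))  # argmin takes the first (smallest-index) tie
    if err[best] > tol:
        raise ValueError(
            f"no pair within {tol} of target distance {target_d} "
            f"(closest: {d[best]:.4f})"
        )
    i, j = int(iu[0][best]), int(iu[1][best])
    return pool.odors[i], pool.odors[j]
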
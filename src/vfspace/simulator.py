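"""Sampling-with-replacement simulator of verbal-fluency production.

The retrieval model: a covert elementary sampling step of duration 1/r
seconds draws one tuple uniformly (with replacement) from the 2^i tuples
over the i category members.  A draw succeeds when the sampled tuple is
still admissible — disjoint from the set of already-produced words; the
empty tuple counts as favorable.  With n words produced, 2^(i−n) of the
2^i tuples remain admissible, so the success probability is exactly

    p_{n+1} = 2^(i−n) / 2^i = 2^(−n),

a decreasing geometric sequence with ratio 1/2.  On success one of the
unproduced words (chosen uniformly — the tuple structure is symmetric in
the word identities) is produced at the current time.  The run ends when
all i words are produced or the draw budget is exhausted.

The ``geometric`` mode generalizes the success law to p_{n+1} = q^n for an
arbitrary ratio q ∈ (0, 1) = e^(−1/k), matching logarithmic time courses
with scale k ≠ 1/ln 2.

In the continuum limit dn/dt = r·q^n the cumulative curve is logarithmic,
n(t) = k·ln(1 + rt/k) with k = 1/ln(1/q) (``theoretical_curve``).  Note a
genuine discreteness effect of the coarse ratio q = 1/2: the *mean onset*
of word n is (1/r)·Σ_{m<n} 2^m = (2^n − 1)/r, which lies exactly on
n(t) = k·ln(1 + rt), i.e. a logarithmic curve with scale k = 1/ln 2 but
effective rate parameter r/ln 2.  Curve fits of simulated data recover k
faithfully and the rate only up to that 1/ln 2 factor; see the methods
note.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fbf import LogParams

__all__ = [
    "SimulationConfig",
    "ProductionRecord",
    "admissible_count",
    "simulate_run",
    "simulate_many",
    "theoretical_curve",
    "generate_fixture_set",
]

MODES = ("uniform_tuple", "geometric")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated verbal-fluency experiment.

    i           number of category members (words w1..wi)
    r           draws per second (reciprocal elementary process duration)
    mode        "uniform_tuple" (success ratio fixed at q = 1/2 by the
                all-tuples structure) or "geometric" (explicit ratio q)
    q           success-decay ratio in (0, 1); geometric mode only
    n_runs      independent runs (participants)
    seed        master seed; run j uses seed + j
    max_draws   draw budget per run (waiting times grow as q^(−n))
    exponential_waiting
                replace the deterministic 1/r step by an exponential
                waiting time of the same mean (off by default)
    """

    i: int
    r: float = 1.0
    mode: str = "uniform_tuple"
    q: float | None = None
    n_runs: int = 1
    seed: int = 0
    max_draws: int = 10**6
    exponential_waiting: bool = False

    def __post_init__(self):
        if not 1 <= self.i <= 64:
            raise ValueError(f"i must be in [1, 64], got {self.i}")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "uniform_tuple":
            if self.q is not None and self.q != 0.5:
                raise ValueError("uniform_tuple mode fixes q = 1/2")
            object.__setattr__(self, "q", 0.5)
        else:
            if self.q is None or not 0.0 < self.q < 1.0:
                raise ValueError(f"geometric mode needs q in (0, 1), got {self.q!r}")
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.max_draws < 1:
            raise ValueError(f"max_draws must be >= 1, got {self.max_draws}")

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(f"w{j + 1}" for j in range(self.i))


@dataclass(frozen=True)
class ProductionRecord:
    """One run's produced words with onset times (seconds)."""

    words: tuple[str, ...]
    onsets: np.ndarray
    run_id: int = 0
    seed: int | None = None
    truncated: bool = False  # draw budget exhausted before the last word
    draw_counts: tuple[int, ...] = ()  # draws spent per produced word
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "words", tuple(self.words))
        if onsets.shape != (len(self.words),):
            raise ValueError("words and onsets must have equal length")
        if len(set(self.words)) != len(self.words):
            raise ValueError("repeated word in production record")
        if onsets.size and (onsets[0] <= 0 or np.any(np.diff(onsets) <= 0)):
            raise ValueError("onsets must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.words)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"word": list(self.words), "onset_seconds": self.onsets})


def admissible_count(i: int, produced: int) -> int:
    """Number of tuples disjoint from a produced set of size *produced*:
    2^(i − produced), the favorable-object count of the sampling model."""
    if not 0 <= produced <= i:
        raise ValueError(f"produced must be in [0, {i}], got {produced}")
    return 1 << (i - produced)


def simulate_run(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    run_id: int = 0,
) -> ProductionRecord:
    """Simulate one verbal-fluency run.

    The waiting draws at stage n are geometric with success probability
    q^n (sampled directly, which is distributionally identical to drawing
    tuples one by one).  Onsets are cumulative draws divided by r, or sums
    of exponential waiting times of mean (1/r)/q^n when
    ``exponential_waiting`` is set.
    """
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    words: list[str] = []
    onsets: list[float] = []
    draw_counts: list[int] = []
    remaining = list(config.words)
    draws_left = config.max_draws
    t = 0.0
    truncated = False
    for n in range(config.i):
        p = config.q**n
        if config.exponential_waiting:
            wait = rng.exponential(1.0 / (config.r * p))
            n_draws = max(1, math.ceil(wait * config.r))
            t += wait
        else:
            n_draws = int(rng.geometric(p))
            t += n_draws / config.r
        if n_draws > draws_left:
            truncated = True
            break
        draws_left -= n_draws
        produced = remaining.pop(int(rng.integers(len(remaining))))
        words.append(produced)
        onsets.append(t)
        draw_counts.append(n_draws)
    return ProductionRecord(
        words=tuple(words),
        onsets=np.array(onsets),
        run_id=run_id,
        seed=seed,
        truncated=truncated,
        draw_counts=tuple(draw_counts),
        config=dataclasses.asdict(config),
    )


def simulate_many(config: SimulationConfig) -> list[ProductionRecord]:
    """Simulate ``config.n_runs`` independent runs; run j is seeded with
    ``config.seed + j`` for reproducibility run by run."""
    return [
        simulate_run(config, rng=config.seed + j, run_id=j)
        for j in range(config.n_runs)
    ]


def theoretical_curve(config: SimulationConfig) -> LogParams:
    """Continuum-limit logarithmic parameters of the configured process.

    Solving dn/dt = r·q^n gives n(t) = k·ln(1 + rt/k) with k = 1/ln(1/q)
    (uniform_tuple: k = 1/ln 2 ≈ 1.4427); r passes through unchanged.
    """
    return LogParams(k=1.0 / math.log(1.0 / config.q), r=config.r)


def generate_fixture_set(config: SimulationConfig, out: str | Path) -> list[Path]:
    """Write one CSV per run (word, onset_seconds) plus a JSON manifest.

    Deterministic: the same config and seed produce byte-identical files.
    Returns the written paths (manifest last).
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    records = simulate_many(config)
    paths = []
    for rec in records:
        path = out / f"run_{rec.run_id:04d}.csv"
        rec.to_frame().to_csv(path, index=False)
        paths.append(path)
    manifest = {
        "config": dataclasses.asdict(config),
        "runs": [
            {
                "file": p.name,
                "run_id": rec.run_id,
                "seed": rec.seed,
                "n_words": len(rec),
                "truncated": rec.truncated,
            }
            for p, rec in zip(paths, records)
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths.append(manifest_path)
    return paths
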
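"""Benchmark instance generator for diploid fragment phasing.

Instances follow the classic benchmark design for single individual
haplotyping: a heterozygous haplotype pair of length ``l`` (h1 drawn iid
Bernoulli(0.5), h2 its complement — every site is a heterozygous SNP, so
allele content carries no information and only the geometry (l, c, e)
matters), covered by fragments at mean per-column coverage ``c``, with each
observed allele flipped independently with probability ``e``. The standard
grid is l in {100, 350, 700}, c in {3, 5, 8, 10}, e in {0.1, 0.2, 0.3}.

By default each fragment is a full-length row of the SNP matrix with
independent internal gaps (rate 0.2), the mate-pair-style gapped rows of
the classic benchmark matrices; the fragment count is set so the *observed*
per-column coverage averages c. Phasing difficulty is then governed by
(l, c, e) rather than by read contiguity, and every column is almost surely
observed by both chromosome copies. Contiguous sub-block fragments (with
``frag_len_min``/``frag_len_max`` spans shorter than ``l``) remain available
for experiments on read-length effects, where switch errors between weakly
linked regions become the dominant failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import HaplotypePair, SNPMatrix, write_fragment_matrix, write_haplotypes
from .ncm import NCMParams
from .pipeline import Mode, reconstruct

MODES: tuple[Mode, ...] = ("initial_only", "ncm_random", "ncmhap")

#: the standard benchmark grid: (length, coverage, error-rate)
DEFAULT_GRID_L = (100, 350, 700)
DEFAULT_GRID_C = (3, 5, 8, 10)
DEFAULT_GRID_E = (0.1, 0.2, 0.3)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated phasing instance.

    ``frag_len_min``/``frag_len_max`` bound the contiguous span of a
    fragment before gapping and default to the full block length ``l``;
    ``internal_gap_rate`` masks each covered position independently
    (default 0.2). The defaults emulate the gapped full-length rows of the
    classic phasing benchmark matrices; see the methods note for the
    calibration behind them.
    """

    l: int
    c: float
    e: float
    frag_len_min: int | None = None
    frag_len_max: int | None = None
    internal_gap_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l < 2:
            raise ValueError("haplotype length l must be >= 2")
        if self.c <= 0:
            raise ValueError("coverage c must be > 0")
        if not 0 <= self.e < 0.5:
            raise ValueError("error rate e must be in [0, 0.5)")
        if not 0 <= self.internal_gap_rate < 1:
            raise ValueError("internal_gap_rate must be in [0, 1)")
        if self.frag_len_min is None:
            object.__setattr__(self, "frag_len_min", self.l)
        if self.frag_len_max is None:
            object.__setattr__(self, "frag_len_max", max(self.frag_len_min, self.l))
        if not 2 <= self.frag_len_min <= self.frag_len_max <= self.l:
            raise ValueError(
                f"need 2 <= frag_len_min <= frag_len_max <= l, got "
                f"[{self.frag_len_min}, {self.frag_len_max}] with l={self.l}"
            )

    @property
    def mean_frag_len(self) -> float:
        return (self.frag_len_min + self.frag_len_max) / 2.0

    @property
    def n_fragments(self) -> int:
        # observed per-column coverage = n * mean_span * (1-gap_rate) / l
        dense = self.mean_frag_len * (1.0 - self.internal_gap_rate)
        return max(2, round(self.c * self.l / dense))


@dataclass
class Instance:
    """A simulated instance with its generator bookkeeping."""

    matrix: SNPMatrix
    truth: HaplotypePair
    origin: np.ndarray       # per-fragment true chromosome copy, 1 or 2
    flips: np.ndarray        # per-fragment count of injected allele flips
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def total_flips(self) -> int:
        return int(self.flips.sum())

    @property
    def total_observed(self) -> int:
        return int(self.matrix.observed.sum())

    def write(self, fragments_path, truth_path) -> None:
        """Write the plain matrix format plus the two-line truth file."""
        write_fragment_matrix(self.matrix, fragments_path)
        write_haplotypes(self.truth, truth_path)


def simulate_instance(cfg: SimulationConfig) -> Instance:
    """Generate one instance from its config (deterministic in cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    h1 = rng.integers(0, 2, size=cfg.l, dtype=np.uint8)
    h2 = (1 - h1).astype(np.uint8)
    haplos = np.stack([h1, h2])
    truth = HaplotypePair("".join(map(str, h1)), "".join(map(str, h2)))

    m = cfg.n_fragments
    alleles = np.zeros((m, cfg.l), dtype=np.uint8)
    observed = np.zeros((m, cfg.l), dtype=bool)
    origin = np.zeros(m, dtype=np.int64)
    flips = np.zeros(m, dtype=np.int64)
    for i in range(m):
        while True:  # redraw until the fragment observes >= 1 site
            src = int(rng.integers(1, 3))
            length = int(rng.integers(cfg.frag_len_min, cfg.frag_len_max + 1))
            start = int(rng.integers(0, cfg.l - length + 1))
            cover = np.zeros(cfg.l, dtype=bool)
            cover[start : start + length] = True
            if cfg.internal_gap_rate > 0:
                cover[start : start + length] &= (
                    rng.random(length) >= cfg.internal_gap_rate
                )
            if cover.any():
                break
        row = haplos[src - 1].copy()
        flip = cover & (rng.random(cfg.l) < cfg.e)
        row[flip] = 1 - row[flip]
        alleles[i] = np.where(cover, row, 0)
        observed[i] = cover
        origin[i] = src
        flips[i] = int(flip.sum())
    matrix = SNPMatrix(alleles, observed)
    return Instance(matrix, truth, origin, flips, cfg)


def _instance_seed(base_seed: int, index: int) -> int:
    """Deterministic per-instance seed, kept below 2**31."""
    return (base_seed * 1_000_003 + index * 7_919 + 17) % (2**31 - 1)


def simulate_batch(
    cfg_grid: list[SimulationConfig],
    n_instances: int,
    base_seed: int = 0,
    params: NCMParams | None = None,
    modes: tuple[Mode, ...] = MODES,
) -> tuple[list[list[Instance]], pd.DataFrame]:
    """Run the three-mode ablation over a grid of configurations.

    Each grid cell gets ``n_instances`` independently seeded instances; every
    instance is reconstructed in each requested mode. Returns the instances
    (one list per cell) and a summary table with columns
    (l, c, e, mode, n, mean_rr, sd_rr, mean_mec).
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    params = params or NCMParams()
    all_instances: list[list[Instance]] = []
    records = []
    counter = 0
    for cfg in cfg_grid:
        cell_instances: list[Instance] = []
        per_mode_rr: dict[str, list[float]] = {mode: [] for mode in modes}
        per_mode_mec: dict[str, list[int]] = {mode: [] for mode in modes}
        for _ in range(n_instances):
            seed = _instance_seed(base_seed, counter)
            counter += 1
            inst = simulate_instance(
                SimulationConfig(
                    l=cfg.l,
                    c=cfg.c,
                    e=cfg.e,
                    frag_len_min=cfg.frag_len_min,
                    frag_len_max=cfg.frag_len_max,
                    internal_gap_rate=cfg.internal_gap_rate,
                    seed=seed,
                )
            )
            cell_instances.append(inst)
            for mode in modes:
                res = reconstruct(
                    inst.matrix, params, mode=mode, seed=seed, truth=inst.truth
                )
                per_mode_rr[mode].append(res.rr)
                per_mode_mec[mode].append(res.mec)
        all_instances.append(cell_instances)
        for mode in modes:
            rr = np.asarray(per_mode_rr[mode], dtype=np.float64)
            records.append(
                {
                    "l": cfg.l,
                    "c": cfg.c,
                    "e": cfg.e,
                    "mode": mode,
                    "n": n_instances,
                    "mean_rr": float(rr.mean()),
                    "sd_rr": float(rr.std(ddof=1)) if n_instances > 1 else 0.0,
                    "mean_mec": float(np.mean(per_mode_mec[mode])),
                }
            )
    return all_instances, pd.DataFrame.from_records(records)


def default_grid(
    ls=DEFAULT_GRID_L, cs=DEFAULT_GRID_C, es=DEFAULT_GRID_E
) -> list[SimulationConfig]:
    """The full benchmark grid as a list of configs (l-major order)."""
    return [
        SimulationConfig(l=l, c=c, e=e) for l in ls for c in cs for e in es
    ]
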
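"""Training-corpus generation, storage, standardization and splitting.

Each record pairs a 9-vector of log-uniform rate factors with the mean
stress trace of ``replicates`` independent twitches at those factors.
Records are seeded individually from ``(master_seed, record_index,
replicate)`` so any record can be regenerated standalone, generation can be
chunked or resumed, and the whole corpus is bit-reproducible.

Datasets live in a single chunked HDF5 container (traces, factors,
metadata) with the standardization statistics stored alongside the data;
validation and inference-time targets are always standardized with the
training statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .kinetics import RateFactors
from .params import FACTOR_NAMES, ModelConfig
from .simulate import average_replicates


@dataclass
class TrainingDataset:
    """In-memory corpus of (trace, factor) pairs.

    ``factors`` are stored as log10 multipliers.  ``mean_``/``std_`` are the
    scalar standardization statistics over all *training* timepoints (None
    until :func:`standardize` has run).  ``varied`` names the factors that
    were sampled; frozen factors are recorded in ``frozen``.
    """

    traces: np.ndarray                 # (N, n_steps) stress, mN/mm^2
    factors: np.ndarray                # (N, n_varied) log10 factors
    varied: tuple[str, ...] = FACTOR_NAMES
    frozen: dict[str, float] = field(default_factory=dict)
    bounds: tuple[float, float] = (-1.0, 2.0)   # log10 prior box
    split: np.ndarray | None = None    # 0 train / 1 validation
    mean_: float | None = None
    std_: float | None = None
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=np.float32)
        self.factors = np.asarray(self.factors, dtype=np.float64)
        if self.traces.shape[0] != self.factors.shape[0]:
            raise ValueError("traces and factors must have equal length")

    @property
    def n_records(self) -> int:
        return self.traces.shape[0]

    # -- views ------------------------------------------------------------
    def _mask(self, which: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("dataset has not been split yet")
        return self.split == (1 if which == "validation" else 0)

    def training(self) -> tuple[np.ndarray, np.ndarray]:
        m = self._mask("training")
        return self.traces[m], self.factors[m]

    def validation(self) -> tuple[np.ndarray, np.ndarray]:
        m = self._mask("validation")
        return self.traces[m], self.factors[m]

    # -- factor scaling ----------------------------------------------------
    def scale_factors(self, log10_factors: np.ndarray) -> np.ndarray:
        """Affine map of log10 factors onto the unit box of the prior."""
        lo, hi = self.bounds
        return (np.asarray(log10_factors) - lo) / (hi - lo)

    def unscale_factors(self, unit: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds
        return np.asarray(unit) * (hi - lo) + lo

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=self.traces,
                             chunks=(min(256, self.n_records),
                                     self.traces.shape[1]),
                             compression="gzip", compression_opts=1)
            f.create_dataset("factors", data=self.factors)
            if self.split is not None:
                f.create_dataset("split", data=self.split.astype(np.int8))
            f.attrs["varied"] = json.dumps(list(self.varied))
            f.attrs["frozen"] = json.dumps(self.frozen)
            f.attrs["bounds"] = list(self.bounds)
            f.attrs["standardized"] = self.standardized
            if self.mean_ is not None:
                f.attrs["mean"] = self.mean_
                f.attrs["std"] = self.std_
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path: str | Path) -> "TrainingDataset":
        with h5py.File(path, "r") as f:
            ds = cls(
                traces=f["traces"][:],
                factors=f["factors"][:],
                varied=tuple(json.loads(f.attrs["varied"])),
                frozen=json.loads(f.attrs["frozen"]),
                bounds=tuple(f.attrs["bounds"]),
                split=f["split"][:] if "split" in f else None,
                meta=json.loads(f.attrs["meta"]),
            )
            ds.standardized = bool(f.attrs["standardized"])
            if "mean" in f.attrs:
                ds.mean_ = float(f.attrs["mean"])
                ds.std_ = float(f.attrs["std"])
        return ds


# ---------------------------------------------------------------------------
# sampling and generation

def sample_rate_factors(n: int, seed: int | tuple = 0,
                        bounds: tuple[float, float] = (0.1, 100.0),
                        n_factors: int = len(FACTOR_NAMES)) -> np.ndarray:
    """i.i.d. log-uniform factors over the prior box, shape (n, n_factors).

    Returned as multipliers; ``log10`` of the output is uniform on
    ``[log10(lo), log10(hi)]``.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("invalid factor bounds")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exp = rng.uniform(np.log10(lo), np.log10(hi), size=(n, n_factors))
    return 10.0 ** exp


def record_factors(master_seed: int | tuple, index: int,
                   varied: tuple[str, ...],
                   bounds: tuple[float, float] = (0.1, 100.0),
                   center: RateFactors | None = None) -> RateFactors:
    """The factor vector of record ``index`` (standalone-regenerable).

    Varied coordinates are log-uniform over ``bounds``; the rest stay at the
    values of ``center`` (default all 1).
    """
    base = (master_seed,) if isinstance(master_seed, int) else tuple(master_seed)
    vals = sample_rate_factors(1, seed=base + (int(index),), bounds=bounds,
                               n_factors=len(varied))[0]
    fac = center if center is not None else RateFactors()
    return fac.replace(**dict(zip(varied, vals)))


def generate_dataset(n_combos: int, replicates: int, config: ModelConfig,
                     seed: int | tuple = 0,
                     varied: tuple[str, ...] = FACTOR_NAMES,
                     center: RateFactors | None = None,
                     bounds: tuple[float, float] = (0.1, 100.0),
                     path: str | Path | None = None,
                     progress: bool = False) -> TrainingDataset:
    """Simulate the corpus: ``n_combos`` records of ``replicates``-averaged
    twitches (default replicate count for production corpora is 50).

    ``varied`` selects which factors are sampled; the others are frozen at
    ``center`` (the reduced-dimension mode used for intervention studies).
    If ``path`` exists with a partial corpus from the same seed/config it is
    resumed, never duplicated.
    """
    if n_combos < 1 or replicates < 1:
        raise ValueError("n_combos and replicates must be >= 1")
    base = (seed,) if isinstance(seed, int) else tuple(seed)
    n_steps = config.n_steps
    traces = np.zeros((n_combos, n_steps), dtype=np.float32)
    factors = np.zeros((n_combos, len(varied)))
    start = 0
    if path is not None and Path(path).exists():
        prev = TrainingDataset.load(path)
        if (prev.meta.get("seed") == str(base)
                and prev.meta.get("config") == config.hash()
                and prev.traces.shape[1] == n_steps
                and tuple(prev.varied) == tuple(varied)):
            start = min(prev.meta.get("complete", prev.n_records), n_combos)
            traces[:start] = prev.traces[:start]
            factors[:start] = prev.factors[:start]
    frozen = {}
    if center is not None:
        frozen = {n: getattr(center, n) for n in FACTOR_NAMES
                  if n not in varied}
    meta = {"seed": str(base), "config": config.hash(),
            "replicates": replicates, "complete": start}
    it = range(start, n_combos)
    if progress:
        from tqdm import tqdm
        it = tqdm(it, initial=start, total=n_combos)
    ds = TrainingDataset(traces=traces, factors=factors, varied=tuple(varied),
                         frozen=frozen,
                         bounds=(np.log10(bounds[0]), np.log10(bounds[1])),
                         meta=meta)
    for i in it:
        fac = record_factors(base, i, varied, bounds, center)
        tr = average_replicates(fac, config, n=replicates,
                                seed=base + (int(i),))
        traces[i] = tr.stress
        factors[i] = np.log10(fac.to_array(varied))
        meta["complete"] = i + 1
        if path is not None and ((i + 1) % 500 == 0):
            ds.save(path)
    meta["complete"] = n_combos
    if path is not None:
        ds.save(path)
    return ds


# ---------------------------------------------------------------------------
# split and standardization

def split(dataset: TrainingDataset, validation_fraction: float = 0.01,
          seed: int | tuple = 0) -> TrainingDataset:
    """Label a disjoint, exhaustive, seed-reproducible validation split
    (default 1%)."""
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError("validation fraction must be in (0, 1)")
    n = dataset.n_records
    n_val = int(round(n * validation_fraction))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.choice(n, size=n_val, replace=False)] = 1
    dataset.split = labels
    return dataset

def standardize(dataset: TrainingDataset) -> TrainingDataset:
    """Standardize traces with the global training-split mean and std.

    One scalar mean and std over all training timepoints ("global"
    statistics); the same stored values are applied to validation records
    and, downstream, to any inference-time target trace.
    """
    if dataset.standardized:
        return dataset
    tr, _ = dataset.training()
    if tr.size == 0:
        raise ValueError("training split is empty")
    mean = float(tr.mean())
    std = float(tr.std())
    if std == 0.0:
        raise ValueError("training traces have zero variance")
    dataset.traces = ((dataset.traces - mean) / std).astype(np.float32)
    dataset.mean_, dataset.std_ = mean, std
    dataset.standardized = True
    return dataset


def unstandardize(dataset: TrainingDataset) -> TrainingDataset:
    """Invert :func:`standardize` (affine round trip)."""
    if not dataset.standardized:
        return dataset
    dataset.traces = (dataset.traces * dataset.std_ + dataset.mean_).astype(
        np.float32)
    dataset.standardized = False
    return dataset


def standardize_trace(trace: np.ndarray, dataset: TrainingDataset) -> np.ndarray:
    """Standardize an inference-time target with the training statistics."""
    if dataset.mean_ is None:
        raise ValueError("dataset has no stored standardization statistics")
    return (np.asarray(trace, dtype=float) - dataset.mean_) / dataset.std_
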
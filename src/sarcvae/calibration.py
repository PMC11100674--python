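"""Steady-state occupancy measurements used to calibrate the model.

Two printed anchors pin the kinetic scheme:

* at resting (diastolic) calcium about half the myosin heads sit in the
  super-relaxed state (the DRX<->SRX pair balances at 50 s^-1 each way);
* at maximal activation (pCa 4) roughly 10% of crossbridges are attached
  (states 2, 3 or 4).

Both are measured by holding calcium constant, initializing from the
steady-state distribution, simulating at 1 ms steps and averaging the
occupancy over time and replicate seeds (discarding a short transient).
"""

from __future__ import annotations

import numpy as np

from .params import ModelConfig, reduced_lattice_config
from .simulate import state_occupancy


def measure_srx_fraction(config: ModelConfig | None = None,
                         n_seeds: int = 20, seed: int = 0,
                         hold_pca: float = 7.0,
                         duration_ms: float = 2000.0,
                         discard_ms: float = 200.0) -> tuple[float, float]:
    """Time/replicate-averaged SRX occupancy at held diastolic calcium.

    Returns (mean, standard error over seeds).
    """
    cfg = config or reduced_lattice_config()
    cfg = ModelConfig.from_dict(cfg.to_dict())
    cfg.duration = duration_ms
    lo = int(discard_ms / cfg.dt)
    vals = [float(np.mean(state_occupancy(cfg, seed=(seed, i),
                                          hold_pca=hold_pca).srx_fraction[lo:]))
            for i in range(n_seeds)]
    return float(np.mean(vals)), float(np.std(vals) / np.sqrt(n_seeds))


def measure_bound_fraction(config: ModelConfig | None = None,
                           n_seeds: int = 20, seed: int = 0,
                           hold_pca: float = 4.0,
                           duration_ms: float = 1000.0,
                           discard_ms: float = 200.0) -> tuple[float, float]:
    """Steady-state attached fraction (states 2+3+4) at maximal activation."""
    cfg = config or reduced_lattice_config()
    cfg = ModelConfig.from_dict(cfg.to_dict())
    cfg.duration = duration_ms
    lo = int(discard_ms / cfg.dt)
    vals = [float(np.mean(state_occupancy(cfg, seed=(seed, i),
                                          hold_pca=hold_pca).bound_fraction[lo:]))
            for i in range(n_seeds)]
    return float(np.mean(vals)), float(np.std(vals) / np.sqrt(n_seeds))
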
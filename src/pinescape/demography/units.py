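"""Conversion of coalescent-model parameters to absolute units.

Times simulated in generations convert to years by the generation time;
published split times estimated under one (generation time, yearly mutation
rate) pair rescale to another pair multiplicatively: a yearly mutation rate
scales the per-generation rate as mu_gen = mu_year * gen_years, and
estimated times in years scale as t_new = t_old * (gen_new / gen_old) *
(mu_old / mu_new).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


def to_absolute_units(
    times_generations: Mapping[str, float],
    mu_per_year: float,
    gen_years: float,
) -> dict[str, float]:
    """Convert split times in generations to years.

    ``mu_per_year`` and ``gen_years`` must be positive; the per-generation
    mutation rate implied by the pair is returned under ``"mu_per_gen"``.
    """
    if mu_per_year <= 0 or gen_years <= 0:
        raise ValueError("mutation rate and generation time must be positive")
    out = {f"{k}_years": float(v) * gen_years for k, v in times_generations.items()}
    if any(v < 0 for v in times_generations.values()):
        raise ValueError("times must be non-negative")
    out["mu_per_gen"] = mu_per_year * gen_years
    return out


def rescale_times(
    times_years_old: float | np.ndarray,
    gen_old: float,
    mu_old: float,
    gen_new: float,
    mu_new: float,
) -> float | np.ndarray:
    """Rescale time estimates to a different generation time and mutation rate.

    ``t_new = t_old * (gen_new / gen_old) * (mu_old / mu_new)``; swapping the
    old and new constants inverts the transformation.
    """
    vals = np.asarray(times_years_old, dtype=float)
    for name, v in (("gen_old", gen_old), ("mu_old", mu_old),
                    ("gen_new", gen_new), ("mu_new", mu_new)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if (vals < 0).any():
        raise ValueError("times must be non-negative")
    out = vals * (gen_new / gen_old) * (mu_old / mu_new)
    return float(out) if np.isscalar(times_years_old) else out
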
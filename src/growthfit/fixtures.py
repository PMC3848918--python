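"""Synthetic growth-curve generator with known ground truth.

Every test and example dataset in the package is produced here: the truth
parameters are simulated through the registry, noise is applied per
replicate from independent seeded substreams, and a manifest records
everything needed to regenerate the data bit-for-bit.

Noise models
------------
``additive_gaussian``          value + N(0, sigma^2) — plate-reader style
                               measurement error on the signal scale.
``multiplicative_lognormal``   value * exp(N(0, sigma^2)) — keeps values
                               positive, appropriate for log-scale fitting.
Noise touches only the values; times are exact.

Default study conditions (model truths, grids, noise levels) live in
:data:`DEFAULT_SCENARIOS`; they are the conditions the test-suite recovery
and noise-consistency checks run under.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import TimeSeries, ValidationError
from .registry import Registry, get_default_registry

NOISE_MODELS = ("none", "additive_gaussian", "multiplicative_lognormal")


@dataclass(frozen=True)
class GenerationSpec:
    """Recipe for one synthetic dataset (possibly several replicates)."""

    model_id: str
    truth: Mapping[str, float]
    times: tuple  # (start, stop, step); stop inclusive up to step/2
    noise_model: str = "none"
    sigma: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        start, stop, step = self.times
        if not step > 0:
            raise ValidationError(f"step must be > 0 (got {step})")
        if not stop > start:
            raise ValidationError("stop must exceed start")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0 (got {self.sigma})")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )
        if self.noise_model != "none" and self.sigma == 0:
            raise ValidationError("noisy generation requires sigma > 0")
        object.__setattr__(self, "truth", dict(self.truth))
        object.__setattr__(self, "times", tuple(float(x) for x in self.times))

    def time_grid(self) -> np.ndarray:
        start, stop, step = self.times
        return np.arange(start, stop + step / 2.0, step)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "truth": {k: float(v) for k, v in self.truth.items()},
            "times": list(self.times),
            "noise_model": self.noise_model,
            "sigma": float(self.sigma),
            "n_replicates": int(self.n_replicates),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerationSpec":
        return cls(
            model_id=d["model_id"],
            truth=dict(d["truth"]),
            times=tuple(d["times"]),
            noise_model=d.get("noise_model", "none"),
            sigma=float(d.get("sigma", 0.0)),
            n_replicates=int(d.get("n_replicates", 1)),
            seed=int(d.get("seed", 0)),
        )


def generate_curve(spec: GenerationSpec, *,
                   registry: Registry | None = None):
    """Simulate the truth and apply per-replicate noise.

    Returns ``(replicates, manifest)`` where ``replicates`` is a list of
    TimeSeries and ``manifest`` records the spec and the per-replicate child
    seeds.  Replicate noise draws come from independent substreams spawned
    from the seed, so the output is deterministic given the spec.
    """
    reg = registry if registry is not None else get_default_registry()
    grid = spec.time_grid()
    clean = reg.simulate(spec.model_id, spec.truth, grid).values

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    replicates = []
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        if spec.noise_model == "none":
            values = clean.copy()
        elif spec.noise_model == "additive_gaussian":
            values = clean + rng.normal(0.0, spec.sigma, size=clean.size)
        else:  # multiplicative_lognormal
            values = clean * np.exp(rng.normal(0.0, spec.sigma, size=clean.size))
        replicates.append(
            TimeSeries(grid, values, name=f"{spec.model_id}_rep{i + 1}")
        )
    manifest = {
        "spec": spec.to_dict(),
        "n_points": int(grid.size),
        "replicate_names": [ts.name for ts in replicates],
    }
    return replicates, manifest


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

#: Study conditions for the built-in dynamic models: truth parameters on the
#: scale a lab would see (OD-like sigmoids over ~48 h, a tumor weight series
#: over ~80 d, a spheroid radius over 40 time units), with a dense grid of
#: ~100 points and a measurement-noise level per model.
DEFAULT_SCENARIOS: dict[str, dict] = {
    "gompertz": {
        "truth": {"A": 1.0, "mu_max": 0.2, "lambda_": 5.0},
        "times": (0.0, 48.0, 0.5),
        "sigma": 0.02,
    },
    "logistic": {
        "truth": {"A": 1.0, "mu_max": 0.25, "lambda_": 4.0},
        "times": (0.0, 48.0, 0.5),
        "sigma": 0.02,
    },
    "richards": {
        "truth": {"A": 1.0, "mu_max": 0.3, "lambda_": 3.0, "v": 0.5},
        "times": (0.0, 48.0, 0.5),
        "sigma": 0.02,
    },
    "baranyi": {
        "truth": {"y0": 2.0, "y_max": 9.0, "mu_max": 0.8, "v_rate": 0.8,
                  "h0": 2.0, "m_curv": 1.0},
        "times": (0.0, 24.0, 0.25),
        "sigma": 0.05,
    },
    "baranyi_classic": {
        "truth": {"y0": 2.0, "y_max": 9.0, "mu_max": 0.8, "v_rate": 0.8,
                  "h0": 2.0, "m_curv": 1.0},
        "times": (0.0, 24.0, 0.25),
        "sigma": 0.05,
    },
    "h3": {
        # truth on the scale of a solid-tumor weight series (grams vs days)
        "truth": {"M": 7.547, "delta": 5.103e-9, "gamma": 4.630,
                  "theta": 0.004, "P0": 0.2, "t0": 0.0},
        "times": (0.0, 80.0, 0.8),
        "sigma": 0.066,
    },
    "lcf": {
        "truth": {"alpha": 0.2, "delta": 0.05, "lambda_depth": 1.0, "r0": 0.5},
        "times": (0.0, 40.0, 1.0),
        "sigma": 0.05,
    },
    "exp_decay": {
        "truth": {"y0": 2.0, "k": 0.3, "c": 0.2},
        "times": (0.0, 20.0, 0.2),
        "sigma": 0.02,
    },
}


def default_spec(model_id: str, *, noise: bool = False, n_replicates: int = 1,
                 seed: int = 0) -> GenerationSpec:
    """The default GenerationSpec for a built-in dynamic model."""
    scenario = DEFAULT_SCENARIOS[model_id]
    return GenerationSpec(
        model_id=model_id,
        truth=scenario["truth"],
        times=scenario["times"],
        noise_model="additive_gaussian" if noise else "none",
        sigma=scenario["sigma"] if noise else 0.0,
        n_replicates=n_replicates,
        seed=seed,
    )


def make_benchmark_suite(root, *, seed: int = 0,
                         registry: Registry | None = None) -> dict:
    """Write one noiseless and one noisy CSV per built-in dynamic model.

    Files use the measurement CSV dialect (time,value header) and a single
    ``manifest.json`` records the specs and per-file ground truth.  The same
    seed regenerates byte-identical files.  Returns the manifest.
    """
    from .datastore import Measurement, export_measurement_csv

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "datasets": []}
    for i, model_id in enumerate(sorted(DEFAULT_SCENARIOS)):
        for noisy in (False, True):
            spec = default_spec(model_id, noise=noisy,
                                seed=(seed + 1000 * i + int(noisy)) % (2**31))
            replicates, gen_manifest = generate_curve(spec, registry=registry)
            label = f"{model_id}_{'noisy' if noisy else 'clean'}"
            fname = f"{label}.csv"
            m = Measurement.from_timeseries(replicates[0], label)
            export_measurement_csv(m, root / fname)
            manifest["datasets"].append({"file": fname, **gen_manifest})
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
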
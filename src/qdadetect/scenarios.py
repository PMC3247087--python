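"""Synthetic weak-marginal / strong-bivariate interaction scenarios.

Each generator plants a two-dimensional signal whose single coordinates
are nearly useless for telling the two classes apart, while the joint
distribution separates them cleanly:

``linear``
    Two bivariate Gaussians sharing a strongly correlated covariance,
    class means at (0, 0) and (-1, 1).  The mean shift runs against the
    correlation axis, so each marginal overlaps heavily but the pair is
    almost linearly separable.
``xor``
    Class 0 uniform on the two quadrants where the coordinates share a
    sign, class 1 on the two where they differ — the classical XOR
    layout.  Both marginals are identical between classes.
``circular``
    Standard bivariate normal points labelled by squared radius: class 0
    inside ``r0sq``, class 1 outside ``r1sq`` (``r0sq <= r1sq`` allows a
    gap).  Both marginals are symmetric and overlap.
``vshape``
    Uniform bands above the V-curve ``x2 = |x1|``; class 1 occupies a
    disjoint higher band.  ``x1`` is pure noise marginally; ``x2`` is
    only mildly informative.

High-dimensional study sets are obtained by appending independent
standard-normal noise columns (:func:`add_noise_features`) or generated
as pure noise (:func:`simulate_noise_only`).

All generators are deterministic given their seed.  Distinct operations
draw from distinct, salted PCG64 streams so that e.g. appending noise
never perturbs the signal draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .dataset import LabeledDataset

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "default_params",
    "simulate_scenario",
    "add_noise_features",
    "simulate_noise_only",
]

SCENARIOS = ("linear", "xor", "circular", "vshape")

# Median of a chi-square with 2 df: balanced circular classes by default.
_CHI2_2_MEDIAN = 2.0 * math.log(2.0)

_FEATURE_NAMES = {
    "linear": ("Z1", "Z2"),
    "xor": ("X1", "X2"),
    "circular": ("R1", "R2"),
    "vshape": ("V1", "V2"),
}

# Salts keep the per-operation PCG64 streams disjoint for a shared seed.
_SALT_SCENARIO = 11
_SALT_NOISE = 13
_SALT_NOISE_ONLY = 17


def _rng(salt: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([salt, int(seed)])


def default_params(scenario_id: str) -> dict[str, Any]:
    """Default parameter record for one of the four scenarios."""
    if scenario_id == "linear":
        return {
            "mu0": (0.0, 0.0),
            "mu1": (-1.0, 1.0),
            "cov": ((1.0, 0.9), (0.9, 1.0)),
        }
    if scenario_id == "xor":
        return {"half_width": 1.0}
    if scenario_id == "circular":
        return {"r0sq": _CHI2_2_MEDIAN, "r1sq": _CHI2_2_MEDIAN}
    if scenario_id == "vshape":
        return {
            "offset0": 0.0,
            "width0": 0.3,
            "offset1": 0.5,
            "width1": 0.3,
            "x1_halfwidth": 1.0,
        }
    raise ValueError(f"unknown scenario {scenario_id!r}; choose from {SCENARIOS}")


@dataclass
class ScenarioSpec:
    """Parameters of one planted bivariate interaction pattern.

    ``params`` overrides entries of :func:`default_params`; omitted keys
    keep their defaults.
    """

    scenario_id: str
    n0: int = 40
    n1: int = 40
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario_id!r}; choose from {SCENARIOS}"
            )
        if self.n0 < 0 or self.n1 < 0 or self.n0 + self.n1 < 1:
            raise ValueError("need n0 >= 0, n1 >= 0 and n0 + n1 >= 1")
        merged = default_params(self.scenario_id)
        merged.update(self.params)
        self.params = merged
        self._validate_params()

    def _validate_params(self) -> None:
        p = self.params
        if self.scenario_id == "linear":
            cov = np.asarray(p["cov"], dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError("linear covariance must be symmetric 2x2")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "linear covariance is not positive definite"
                ) from exc
        elif self.scenario_id == "circular":
            if p["r0sq"] > p["r1sq"]:
                raise ValueError("circular requires r0sq <= r1sq")
            if p["r0sq"] <= 0:
                raise ValueError("circular requires r0sq > 0")
        elif self.scenario_id == "vshape":
            if p["width0"] <= 0 or p["width1"] <= 0:
                raise ValueError("vshape band widths must be positive")

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=int(seed))


def _draw_linear(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    p = spec.params
    chol = np.linalg.cholesky(np.asarray(p["cov"], dtype=float))
    x0 = np.asarray(p["mu0"], float) + rng.standard_normal((spec.n0, 2)) @ chol.T
    x1 = np.asarray(p["mu1"], float) + rng.standard_normal((spec.n1, 2)) @ chol.T
    return x0, x1


def _draw_xor(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    h = float(spec.params["half_width"])

    def quadrant_sample(n: int, same_sign: bool) -> np.ndarray:
        # Uniform over the union of two opposite quadrants: pick one of
        # the two quadrants fairly, then a uniform point inside it.
        u = rng.uniform(0.0, h, size=(n, 2))
        flip = np.where(rng.integers(0, 2, size=n) == 1, -1.0, 1.0)
        sign2 = flip if same_sign else -flip
        return np.column_stack([u[:, 0] * flip, u[:, 1] * sign2])

    return quadrant_sample(spec.n0, True), quadrant_sample(spec.n1, False)


def _draw_circular(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    r0sq = float(spec.params["r0sq"])
    r1sq = float(spec.params["r1sq"])

    def rejection(n: int, keep_inner: bool) -> np.ndarray:
        out: list[np.ndarray] = []
        got = 0
        for _ in range(10_000):
            if got >= n:
                break
            cand = rng.standard_normal((max(4 * (n - got), 16), 2))
            r2 = np.einsum("ij,ij->i", cand, cand)
            mask = r2 <= r0sq if keep_inner else r2 > r1sq
            kept = cand[mask]
            out.append(kept)
            got += len(kept)
        else:
            raise RuntimeError(
                "circular rejection sampling failed to reach the requested "
                "class count; radius thresholds leave too little probability"
            )
        return np.concatenate(out)[:n] if out else np.empty((0, 2))

    return rejection(spec.n0, True), rejection(spec.n1, False)


def _draw_vshape(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    p = spec.params
    hw = float(p["x1_halfwidth"])

    def band(n: int, offset: float, width: float) -> np.ndarray:
        x1 = rng.uniform(-hw, hw, size=n)
        x2 = np.abs(x1) + offset + rng.uniform(0.0, width, size=n)
        return np.column_stack([x1, x2])

    return (
        band(spec.n0, float(p["offset0"]), float(p["width0"])),
        band(spec.n1, float(p["offset1"]), float(p["width1"])),
    )


_DRAWERS = {
    "linear": _draw_linear,
    "xor": _draw_xor,
    "circular": _draw_circular,
    "vshape": _draw_vshape,
}


def simulate_scenario(spec: ScenarioSpec) -> LabeledDataset:
    """Draw one two-column dataset from a planted interaction pattern.

    Returns ``spec.n0`` rows labelled 0 followed by ``spec.n1`` rows
    labelled 1.  Identical ``(spec, seed)`` give bit-identical output.
    """
    rng = _rng(_SALT_SCENARIO, spec.seed)
    x0, x1 = _DRAWERS[spec.scenario_id](spec, rng)
    X = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(spec.n0, int), np.ones(spec.n1, int)])
    return LabeledDataset(
        X=X,
        y=y,
        feature_ids=list(_FEATURE_NAMES[spec.scenario_id]),
        signal_columns=[0, 1],
    )


def _fresh_noise_names(existing: set[str], count: int) -> list[str]:
    names: list[str] = []
    i = 1
    while len(names) < count:
        name = f"noise_{i:04d}"
        if name not in existing:
            names.append(name)
        i += 1
    return names


def add_noise_features(
    data: LabeledDataset, p_noise: int, seed: int
) -> LabeledDataset:
    """Append ``p_noise`` i.i.d. standard-normal columns independent of y.

    The noise stream is independent of the scenario stream, so the
    original columns are untouched; ``signal_columns`` are preserved.
    """
    if p_noise < 0:
        raise ValueError("p_noise must be non-negative")
    if p_noise == 0:
        return LabeledDataset(
            X=data.X.copy(),
            y=data.y.copy(),
            feature_ids=list(data.feature_ids),
            signal_columns=list(data.signal_columns),
        )
    rng = _rng(_SALT_NOISE, seed)
    noise = rng.standard_normal((data.n_samples, p_noise))
    return LabeledDataset(
        X=np.hstack([data.X, noise]),
        y=data.y.copy(),
        feature_ids=list(data.feature_ids)
        + _fresh_noise_names(set(data.feature_ids), p_noise),
        signal_columns=list(data.signal_columns),
    )


def simulate_noise_only(n0: int, n1: int, p: int, seed: int) -> LabeledDataset:
    """Pure-noise dataset: labels carry no information about X."""
    if p < 1:
        raise ValueError("need at least one feature")
    if n0 < 0 or n1 < 0 or n0 + n1 < 1:
        raise ValueError("need n0 >= 0, n1 >= 0 and n0 + n1 >= 1")
    rng = _rng(_SALT_NOISE_ONLY, seed)
    X = rng.standard_normal((n0 + n1, p))
    y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    return LabeledDataset(
        X=X,
        y=y,
        feature_ids=_fresh_noise_names(set(), p),
        signal_columns=[],
    )
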
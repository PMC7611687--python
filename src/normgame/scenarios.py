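"""Scenario presets, the heterogeneity sampler, and scenario runners.

Four worked communities exercise the model:

1. A small homogeneous community (n=10) with a severe social dilemma: norm
   payoffs dominate women's weak persuasive power (slopes 0.1), tolerance 0.5.
2. A larger community (n=20) with strong norm enforcement (rates 5), higher
   suffering (1.5) and cheap violence (0.4), where raising the cost of
   violence can backfire.
3. Scenario 1's community with the altruism mechanisms switched on.
4. Scenario 1 plus independent per-couple heterogeneity ("threefold
   reduction to threefold increase"), summarised across women.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import AttitudeModel, CommunityParams, LinearAttitudeModel
from .analysis import changes_from_baseline, summarize_across_women, sweep

__all__ = [
    "ScenarioPreset",
    "build_scenario",
    "sample_heterogeneity",
    "run_scenario",
    "preset_to_config",
    "preset_from_config",
    "save_config",
    "load_config",
    "DEFAULT_SEED",
    "DEFAULT_HETEROGENEITY_TARGETS",
]

DEFAULT_SEED = 20210301
# Per-couple parameters receiving independent multiplicative perturbations.
# Suffering and violence-cost rates by default; effort-cost columns ("d"),
# norm-payoff columns ("n") and slope columns ("f") can be added, at the cost
# of shifting the community-level medians away from the homogeneous baseline
# (sums of n independent factors concentrate at the factor mean, not its
# median).  Tolerance is never perturbed: a multiplicative factor up to 3
# could push t_i past 1.
DEFAULT_HETEROGENEITY_TARGETS = ("s", "c")

_PCT_GRIDS = {
    # Fig-style percent-change axes for the homogeneous baseline community.
    "tau": np.round(np.arange(-100, 91, 10) / 100 + 1.0, 10),
    "alpha": np.round(np.arange(-100, 101, 10) / 100 + 1.0, 10),
    "gamma": np.round(np.concatenate(([-95], np.arange(-90, 101, 10))) / 100 + 1.0, 10),
    "kappa": np.round(np.arange(0, 301, 10) / 100 + 1.0, 10),
}
_ALTRUISM_GRIDS = {
    "b": np.round(np.arange(0, 101, 5) / 100, 10),
    "eta": np.round(np.arange(0, 101, 5) / 100, 10),
    "rho": np.round(np.arange(0, 96, 5) / 1000, 10),
}


@dataclass
class ScenarioPreset:
    """A ready-to-run parameterisation of the game."""

    id: int
    params: CommunityParams
    model: LinearAttitudeModel
    sweep_axes: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None
    description: str = ""


def sample_heterogeneity(
    params: CommunityParams,
    model: AttitudeModel,
    seed: int | None,
    *,
    lo: float = 1.0 / 3.0,
    hi: float = 3.0,
    targets: tuple[str, ...] = DEFAULT_HETEROGENEITY_TARGETS,
) -> tuple[CommunityParams, AttitudeModel]:
    """Perturb per-couple parameters by independent log-uniform factors.

    Each couple's targeted parameters are multiplied by an independent factor
    drawn log-uniformly from ``[lo, hi]`` (default one third to three), the
    symmetric distribution on the multiplicative scale: the median factor is
    ``sqrt(lo*hi)`` (= 1 for the default range).  Targets: ``"s"`` suffering,
    ``"c"`` violence cost, ``"d"`` the woman's effort-cost column, ``"n"``
    the man's norm-payoff column, ``"f"`` the woman's slope column.  The draw
    is fully reproducible from ``seed``.
    """
    if not 0 < lo <= hi:
        raise ValueError("need 0 < lo <= hi")
    unknown = set(targets) - {"s", "c", "d", "n", "f"}
    if unknown:
        raise ValueError(f"unknown heterogeneity targets {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    def draw(n: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    n = params.n
    s, c = params.s.copy(), params.c.copy()
    D, N = params.D.copy(), params.N.copy()
    # draw in fixed target order so the stream is independent of tuple order
    for name in ("s", "c", "d", "n", "f"):
        if name not in targets:
            continue
        factors = draw(n)
        if name == "s":
            s *= factors
        elif name == "c":
            c *= factors
        elif name == "d":
            D *= factors[None, :]
        elif name == "n":
            N *= factors[None, :]
        elif name == "f":
            model = LinearAttitudeModel(
                intercepts=model.intercepts, slopes=model.slopes * factors[None, :]
            )
    new_params = CommunityParams(n=n, s=s, t=params.t, c=c, N=N, D=D)
    if np.any(new_params.t >= 1):  # unreachable: t is never perturbed
        raise ValueError("heterogeneity pushed a tolerance past 1")
    return new_params, model


def build_scenario(
    id: int,
    seed: int | None = None,
    *,
    lo: float = 1.0 / 3.0,
    hi: float = 3.0,
    targets: tuple[str, ...] = DEFAULT_HETEROGENEITY_TARGETS,
) -> ScenarioPreset:
    """Construct one of the four scenario presets.

    Scenario 4 applies the heterogeneity sampler with ``seed`` (default
    ``DEFAULT_SEED``); the other scenarios ignore the sampler arguments.
    """
    if id == 1:
        return ScenarioPreset(
            id=1,
            params=CommunityParams.homogeneous(10),
            model=LinearAttitudeModel.homogeneous(10),
            sweep_axes=dict(_PCT_GRIDS),
            description="homogeneous n=10 community, severe social dilemma",
        )
    if id == 2:
        return ScenarioPreset(
            id=2,
            params=CommunityParams.homogeneous(20, s=1.5, c=0.4, norm=5.0),
            model=LinearAttitudeModel.homogeneous(20),
            sweep_axes={"kappa": _PCT_GRIDS["kappa"]},
            description="strong norms n=20 community; violence-cost sweep",
        )
    if id == 3:
        return ScenarioPreset(
            id=3,
            params=CommunityParams.homogeneous(10),
            model=LinearAttitudeModel.homogeneous(10),
            sweep_axes=dict(_ALTRUISM_GRIDS),
            description="Scenario 1 community with altruism axes active",
        )
    if id == 4:
        seed = DEFAULT_SEED if seed is None else seed
        base = build_scenario(1)
        params, model = sample_heterogeneity(
            base.params, base.model, seed, lo=lo, hi=hi, targets=targets
        )
        return ScenarioPreset(
            id=4,
            params=params,
            model=model,
            sweep_axes=dict(_ALTRUISM_GRIDS),
            seed=seed,
            description="Scenario 1 with per-couple heterogeneity",
        )
    raise ValueError(f"unknown scenario id {id!r}; expected 1, 2, 3 or 4")


def run_scenario(
    id: int,
    out_dir: str | Path | None = None,
    *,
    seed: int | None = None,
    tol: float = 1e-10,
    **sampler_kwargs,
) -> dict[str, pd.DataFrame]:
    """Execute a scenario's default sweeps; optionally write CSVs.

    Returns ``{"sweeps": tidy table}`` plus, for Scenario 4, a
    ``"summary"`` table with min/median/max across women.  When ``out_dir``
    is given, tables are written as ``scenario<id>_sweeps.csv`` (and
    ``..._summary.csv``) next to a ``scenario<id>_run.json`` log recording
    seed, tolerance and package version.
    """
    preset = build_scenario(id, seed=seed, **sampler_kwargs)
    tables = [
        sweep(
            preset.params,
            preset.model,
            param,
            grid,
            scenario=str(id),
            seed=preset.seed,
        )
        for param, grid in preset.sweep_axes.items()
    ]
    result = {"sweeps": pd.concat(tables, ignore_index=True)}
    if id == 4:
        # min/median/max across women of per-woman *changes* from the
        # zero-altruism baseline (what the heterogeneity figure plots)
        result["summary"] = summarize_across_women(
            changes_from_baseline(result["sweeps"])
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in result.items():
            path = out_dir / f"scenario{id}_{name}.csv"
            table.to_csv(path, index=False, float_format="%.12g")
        log = {
            "scenario": id,
            "seed": preset.seed,
            "tol": tol,
            "version": __version__,
        }
        (out_dir / f"scenario{id}_run.json").write_text(
            json.dumps(log, indent=2) + "\n"
        )
    return result


def preset_to_config(preset: ScenarioPreset) -> dict:
    """Serialise a preset to a plain nested dictionary (JSON-compatible)."""
    return {
        "id": preset.id,
        "description": preset.description,
        "seed": preset.seed,
        "params": preset.params.to_dict(),
        "model": preset.model.to_dict(),
        "sweep_axes": {k: np.asarray(v).tolist() for k, v in preset.sweep_axes.items()},
    }


def preset_from_config(config: dict) -> ScenarioPreset:
    model_cfg = dict(config["model"])
    kind = model_cfg.pop("kind", "linear")
    if kind != "linear":
        raise ValueError(f"unsupported attitude model kind {kind!r}")
    return ScenarioPreset(
        id=int(config.get("id", 0)),
        params=CommunityParams.from_dict(config["params"]),
        model=LinearAttitudeModel.from_dict(model_cfg),
        sweep_axes={
            k: np.asarray(v, dtype=float)
            for k, v in config.get("sweep_axes", {}).items()
        },
        seed=config.get("seed"),
        description=config.get("description", ""),
    )


def save_config(preset: ScenarioPreset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(preset_to_config(preset), indent=2) + "\n")


def load_config(path: str | Path) -> ScenarioPreset:
    return preset_from_config(json.loads(Path(path).read_text()))
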
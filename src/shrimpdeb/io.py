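"""File schemas: parameter YAML, observation/forcing/trajectory CSV, bundles.

All delimited files are comma-separated with a mandatory header and '.'
decimals.  User files give temperatures in °C (column ``temp_C``), converted
internally to K by adding 273.15 exactly; a ``temp_K`` column is accepted
when explicitly named.  Numeric output is written at 9 significant digits so
identical inputs give byte-stable files.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DEBParams, ForcingSeries, InvalidInput
from .estimation import DataBundle, UnivariateEntry, ZeroVariateEntry
from .synth import GrowthObservations, ScenarioSpec

__all__ = [
    "read_params",
    "write_params",
    "default_params",
    "read_observations",
    "write_observations",
    "read_forcing",
    "write_forcing",
    "write_trajectory",
    "read_bundle",
    "read_scenario",
]

log = logging.getLogger("shrimpdeb")

FLOAT_FMT = "%.9g"

_PARAM_KEYS = set(DEBParams.default().to_dict())


def default_params() -> DEBParams:
    """The shipped kuruma shrimp parameter file."""
    with resources.files("shrimpdeb.data").joinpath("default_params.yaml").open() as fh:
        return _params_from_mapping(yaml.safe_load(fh) or {}, "default_params.yaml")


def _params_from_mapping(raw: dict, source: str) -> DEBParams:
    if not isinstance(raw, dict):
        raise InvalidInput(f"{source}: parameter file must be a key-value mapping")
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise InvalidInput(f"{source}: unknown parameter keys {sorted(unknown)}")
    missing = _PARAM_KEYS - set(raw) - {"muE", "XK"}
    if missing:
        log.info("%s: keys %s missing, using defaults", source, sorted(missing))
    try:
        return DEBParams(**raw)
    except TypeError as exc:
        raise InvalidInput(f"{source}: {exc}") from exc


def read_params(path) -> DEBParams:
    """Parameters from a YAML file; missing keys fall back to the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _params_from_mapping(raw, str(path))


def write_params(params: DEBParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        {k: (None if v is None else float(v)) for k, v in params.to_dict().items()},
        sort_keys=False))


# ---------------------------------------------------------------------------
# growth observations


def read_observations(path) -> GrowthObservations:
    """Observation table: day, length_cm, weight_g [, sd_length, sd_weight, n]."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise InvalidInput(f"{path}: malformed observation file: {exc}") from exc
    required = {"day", "length_cm", "weight_g"}
    if not required.issubset(df.columns):
        raise InvalidInput(f"{path}: missing required columns "
                           f"{sorted(required - set(df.columns))}")
    for col in required:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise InvalidInput(f"{path}: non-numeric value in column {col!r} "
                               f"at line {bad[0] + 2}")
    day = df["day"].to_numpy(float)
    nonmono = np.nonzero(np.diff(day) <= 0)[0]
    if len(nonmono):
        raise InvalidInput(f"{path}: days not strictly increasing at line "
                           f"{nonmono[0] + 3}")
    return GrowthObservations(
        day=day,
        length_cm=df["length_cm"].to_numpy(float),
        weight_g=df["weight_g"].to_numpy(float),
        sd_length=df["sd_length"].to_numpy(float) if "sd_length" in df else None,
        sd_weight=df["sd_weight"].to_numpy(float) if "sd_weight" in df else None,
        n=df["n"].to_numpy(float) if "n" in df else None,
    )


def write_observations(obs: GrowthObservations, path) -> None:
    obs.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# forcing series


def read_forcing(path, XK: float | None = None) -> ForcingSeries:
    """Forcing table: time_d, temp_C|temp_K, f|X."""
    df = pd.read_csv(path)
    if "time_d" not in df.columns:
        raise InvalidInput(f"{path}: missing required column 'time_d'")
    if "temp_K" in df.columns:
        temp_k = df["temp_K"].to_numpy(float)
    elif "temp_C" in df.columns:
        temp_k = df["temp_C"].to_numpy(float) + 273.15
    else:
        raise InvalidInput(f"{path}: need a 'temp_C' or 'temp_K' column")
    times = df["time_d"].to_numpy(float)
    if "f" in df.columns:
        return ForcingSeries(times, temp_k, f=df["f"].to_numpy(float))
    if "X" in df.columns:
        if XK is None:
            raise InvalidInput(f"{path}: food given as density X but no XK available")
        return ForcingSeries(times, temp_k, X=df["X"].to_numpy(float), XK=XK)
    raise InvalidInput(f"{path}: need an 'f' or 'X' column")


def write_forcing(forcing: ForcingSeries, path) -> None:
    pd.DataFrame({
        "time_d": forcing.times,
        "temp_C": forcing.temperature_K - 273.15,
        "f": forcing.f,
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_trajectory(traj, path) -> None:
    traj.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# estimation bundles and scenarios


def read_bundle(path) -> DataBundle:
    """Estimation bundle YAML: zero_variate entries and univariate curve specs.

    Univariate entries reference their observation tables by path, resolved
    relative to the bundle file.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    zero = [ZeroVariateEntry(
        name=e["name"], observed=float(e["observed"]),
        units=e.get("units", ""),
        temperature_C=e.get("temperature_C"),
        weight=float(e.get("weight", 1.0)),
        label=e.get("label", ""),
    ) for e in raw.get("zero_variate", [])]
    uni = []
    for e in raw.get("univariate", []):
        obs = read_observations(path.parent / e["observations"])
        forcing = None
        if "forcing" in e:
            forcing = read_forcing(path.parent / e["forcing"])
        uni.append(UnivariateEntry(
            name=e["name"], observations=obs,
            quantity=e.get("quantity", "both"),
            temperature_C=e.get("temperature_C"), forcing=forcing,
            f=float(e.get("f", 1.0)), weight=float(e.get("weight", 1.0)),
        ))
    return DataBundle(zero_variate=zero, univariate=uni)


def read_scenario(path) -> ScenarioSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return ScenarioSpec(**raw)
    except TypeError as exc:
        raise InvalidInput(f"{path}: {exc}") from exc
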
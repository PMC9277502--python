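"""Elicited cost/time parameters and their sampling distributions.

Each trial-cost or trial-time quantity elicited from platform-trial experts is
stored as an :class:`ElicitedParameter` -- a mean and standard deviation on the
natural scale, attached to a distribution family (lognormal for costs in 2021
US dollars, normal for times in months) and a unit basis (per trial, per site,
per patient-month, ...).  :class:`ParameterTable` collects the full elicited
set, keyed by ``(name, design_type)`` where ``design_type`` distinguishes
2-group, multigroup and platform trials and ``shared`` marks quantities assumed
identical across designs (site setup and management, recruitment, follow-up,
database management, analyses).

Sampling uses a method-of-moments lognormal parameterization.  Because the
anchoring of the elicited mean is ambiguous (it can be matched to the
arithmetic mean of the lognormal, or placed at its median by using
``ln(mean)`` as the log-scale location), both conventions are implemented via
the ``lognormal_anchor`` switch.  The package default is ``"median"``, which
reproduces the simulated setup-cost scale this model is calibrated against;
see ``docs/methods.md`` for the full rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError

DesignType = Literal["two_group", "multigroup", "platform", "shared"]
Family = Literal["lognormal", "normal"]
Unit = Literal["USD2021", "months"]
LognormalAnchor = Literal["mean", "median"]

DESIGN_TYPES = ("two_group", "multigroup", "platform", "shared")
TRIAL_DESIGN_TYPES = ("two_group", "multigroup", "platform")
BASES = (
    "per_trial",
    "per_site",
    "per_patient",
    "per_patient_month",
    "per_site_month",
    "per_trial_month",
    "per_group_analysis",
    "per_added_group",
)

#: Default anchoring of the elicited mean within the lognormal cost model.
DEFAULT_LOGNORMAL_ANCHOR: LognormalAnchor = "median"


@dataclass(frozen=True)
class ElicitedParameter:
    """One elicited quantity: a cost (USD 2021) or a time (months).

    Parameters
    ----------
    name
        Identifier of the quantity, e.g. ``"site_setup"``.
    design_type
        ``two_group``, ``multigroup`` or ``platform`` for design-specific
        quantities, ``shared`` for quantities assumed constant across designs.
    mean, sd
        Elicited mean and standard deviation on the natural scale.
    family
        ``lognormal`` for costs, ``normal`` for times.
    unit
        ``USD2021`` or ``months``.
    basis
        What one unit of the quantity applies to (per trial, per site, ...).
    """

    name: str
    design_type: str
    mean: float
    sd: float
    family: str
    unit: str
    basis: str

    def __post_init__(self) -> None:
        if self.design_type not in DESIGN_TYPES:
            raise InvalidParameterError(
                f"{self.name}: unknown design_type {self.design_type!r}"
            )
        if not self.mean > 0:
            raise InvalidParameterError(f"{self.name}: mean must be > 0")
        if self.sd < 0:
            raise InvalidParameterError(f"{self.name}: sd must be >= 0")
        if self.family not in ("lognormal", "normal"):
            raise InvalidParameterError(f"{self.name}: unknown family {self.family!r}")
        if self.unit not in ("USD2021", "months"):
            raise InvalidParameterError(f"{self.name}: unknown unit {self.unit!r}")
        if self.basis not in BASES:
            raise InvalidParameterError(f"{self.name}: unknown basis {self.basis!r}")
        # Costs vary lognormally; times vary normally (truncated positive).
        expected_family = "lognormal" if self.unit == "USD2021" else "normal"
        if self.family != expected_family:
            raise InvalidParameterError(
                f"{self.name}: unit {self.unit} requires family {expected_family}"
            )


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Invert the lognormal moment equations.

    Returns ``(mu, sigma)`` such that a lognormal with log-scale location
    ``mu`` and log-scale SD ``sigma`` has arithmetic mean ``mean`` and
    arithmetic SD ``sd``::

        sigma^2 = ln(1 + (sd/mean)^2)
        mu      = ln(mean) - sigma^2 / 2

    With ``sd = 0`` this degenerates to a point mass at ``mean``.
    """
    if not mean > 0:
        raise InvalidParameterError("lognormal mean must be > 0")
    if sd < 0:
        raise InvalidParameterError("lognormal sd must be >= 0")
    sigma_sq = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma_sq / 2.0
    return mu, math.sqrt(sigma_sq)


def _lognormal_params(
    mean: float, sd: float, anchor: str
) -> tuple[float, float]:
    mu, sigma = lognormal_from_moments(mean, sd)
    if anchor == "mean":
        return mu, sigma
    if anchor == "median":
        # Elicited mean placed at the median: location = ln(mean), spread
        # from the same moment inversion.
        return math.log(mean), sigma
    raise InvalidParameterError(f"unknown lognormal_anchor {anchor!r}")


def sample_parameter(
    param: ElicitedParameter,
    rng: np.random.Generator,
    size: int | None = None,
    *,
    lognormal_anchor: LognormalAnchor = DEFAULT_LOGNORMAL_ANCHOR,
):
    """Draw from a parameter's elicited distribution.

    Costs are lognormal; times are normal, constrained positive by rejection
    resampling (redrawing negatives preserves the distribution shape for the
    small-CV time parameters, where clamping would create a point mass at 0).
    Deterministic given the generator state.
    """
    if param.family == "lognormal":
        mu, sigma = _lognormal_params(param.mean, param.sd, lognormal_anchor)
        if sigma == 0.0:
            out = np.full(size if size is not None else (), math.exp(mu))
            return float(out) if size is None else out
        return rng.lognormal(mu, sigma, size)
    # normal time parameter
    if not param.mean > 0:
        raise InvalidParameterError(
            f"{param.name}: positive-constrained normal needs mean > 0"
        )
    if param.sd == 0.0:
        return param.mean if size is None else np.full(size, param.mean)
    n = 1 if size is None else int(size)
    out = rng.normal(param.mean, param.sd, n)
    bad = out <= 0.0
    while bad.any():
        out[bad] = rng.normal(param.mean, param.sd, int(bad.sum()))
        bad = out <= 0.0
    return float(out[0]) if size is None else out


def estimate_moments(responses: Iterable[float]) -> tuple[float, float]:
    """Sample mean and SD (denominator ``n - 1``) of survey responses."""
    arr = np.asarray(list(responses), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 responses")
    return float(arr.mean()), float(arr.std(ddof=1))


#: Every quantity printed in the elicited-parameter table, as
#: (name, design_type) pairs.  Design-specific quantities appear once per
#: trial design; shared quantities once.
REQUIRED_ENTRIES: frozenset[tuple[str, str]] = frozenset(
    [(n, d) for n in (
        "protocol_development",
        "trial_approvals",
        "database_development",
        "protocol_development_time",
        "trial_approvals_time",
        "database_development_time",
    ) for d in TRIAL_DESIGN_TYPES]
    + [(n, "shared") for n in (
        "site_setup",
        "recruitment_per_patient",
        "monthly_followup_per_patient",
        "site_management_per_site_month",
        "database_management_per_month",
        "interim_analysis_per_group",
        "final_analysis_per_group",
    )]
    + [("add_group_cost", "platform"), ("add_group_time", "platform")]
)


class ParameterTable:
    """Collection of :class:`ElicitedParameter` keyed by ``(name, design_type)``."""

    def __init__(self, entries: Iterable[ElicitedParameter] = ()):
        self.entries: dict[tuple[str, str], ElicitedParameter] = {}
        for p in entries:
            self.add(p)

    def add(self, param: ElicitedParameter) -> None:
        key = (param.name, param.design_type)
        if key in self.entries:
            raise InvalidParameterError(f"duplicate parameter {key}")
        self.entries[key] = param

    def lookup(self, name: str, design_type: str) -> ElicitedParameter:
        """Exact lookup by (name, design_type)."""
        try:
            return self.entries[(name, design_type)]
        except KeyError:
            raise KeyError(f"no parameter {(name, design_type)}") from None

    def resolve(self, name: str, design_type: str) -> ElicitedParameter:
        """Lookup with fallback to the ``shared`` entry for the name."""
        p = self.entries.get((name, design_type))
        if p is None:
            p = self.entries.get((name, "shared"))
        if p is None:
            raise KeyError(f"no parameter {name!r} for design {design_type!r}")
        return p

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def is_complete(self) -> bool:
        """True if every printed elicited quantity is present."""
        return REQUIRED_ENTRIES <= set(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "design_type": p.design_type,
                    "mean": p.mean,
                    "sd": p.sd,
                    "family": p.family,
                    "unit": p.unit,
                    "basis": p.basis,
                }
                for p in self.entries.values()
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterTable":
        required = {"name", "design_type", "mean", "sd", "family", "unit", "basis"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidParameterError(f"parameter table missing columns {sorted(missing)}")
        table = cls()
        for _, row in df.iterrows():
            table.add(
                ElicitedParameter(
                    name=str(row["name"]),
                    design_type=str(row["design_type"]),
                    mean=float(row["mean"]),
                    sd=float(row["sd"]),
                    family=str(row["family"]),
                    unit=str(row["unit"]),
                    basis=str(row["basis"]),
                )
            )
        return table

    @classmethod
    def from_csv(cls, path) -> "ParameterTable":
        return cls.from_frame(pd.read_csv(path))


def default_parameter_table() -> ParameterTable:
    """The packaged elicited-parameter table, bit-exact to the printed values."""
    with resources.files("platformsim.data").joinpath(
        "elicited_parameters.csv"
    ).open("rb") as fh:
        table = ParameterTable.from_csv(fh)
    assert table.is_complete()
    return table
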
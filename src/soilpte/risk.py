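"""Deterministic and Monte-Carlo human-health risk assessment.

Implements the US EPA RAGS exposure model for incidental soil ingestion,
particulate inhalation and dermal contact.  For a receptor r and element e
the average daily dose (mg kg^-1 day^-1) per route is

    ADD_ing  = C * IngR * EF * ED * 1e-6 / (BW * AT)
    ADD_inh  = C * InhR * EF * ED / (PEF * BW * AT)
    ADD_derm = C * SA * AF * ABS * EF * ED * 1e-6 / (BW * AT)

with AT = ED * 365 days for non-carcinogens and the configured lifetime
averaging time for carcinogens.  Non-carcinogenic hazard is HQ = sum over
routes of ADD/RfD and HI = sum of HQ over elements; carcinogenic risk is
CR = sum over the configured routes of ADD * SF and TCR = sum of CR.

The Monte-Carlo engine draws exposure parameters from configured
distributions (point, normal, lognormal, uniform, triangular) while holding
concentrations at their central values, runs the full pipeline per draw and
summarises the resulting HI/TCR distributions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .core import ELEMENTS

PATHWAYS = ("ingestion", "inhalation", "dermal")
RECEPTORS = ("child", "adult")

_POSITIVE_REQUIRED = ("BW", "AT_ca", "PEF")


class RiskConfigError(ValueError):
    """Raised for invalid exposure or toxicity configuration."""


# ---------------------------------------------------------------------------
# parameter distributions


@dataclass(frozen=True)
class Dist:
    """A named distribution for one exposure parameter.

    ``lognormal`` is parameterised by its *arithmetic* mean and sd, the form
    exposure-factor tables are printed in; ``normal`` draws are truncated at
    zero to keep physical parameters non-negative.
    """

    kind: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.params[0])
        if self.kind == "normal":
            mean, sd = self.params
            if sd < 0:
                raise RiskConfigError("normal distribution with negative sd")
            return np.clip(rng.normal(mean, sd, n), 0.0, None)
        if self.kind == "lognormal":
            mean, sd = self.params
            if mean <= 0 or sd < 0:
                raise RiskConfigError("lognormal requires mean > 0 and sd >= 0")
            if sd == 0:
                return np.full(n, mean)
            sigma2 = np.log(1.0 + (sd / mean) ** 2)
            mu = np.log(mean) - 0.5 * sigma2
            return rng.lognormal(mu, np.sqrt(sigma2), n)
        if self.kind == "uniform":
            low, high = self.params
            if high < low:
                raise RiskConfigError("uniform with high < low")
            return rng.uniform(low, high, n)
        if self.kind == "triangular":
            low, mode, high = self.params
            if not (low <= mode <= high):
                raise RiskConfigError("triangular requires low <= mode <= high")
            return rng.triangular(low, mode, high, n)
        raise RiskConfigError(f"unknown distribution kind {self.kind!r}")

    @property
    def point(self) -> float:
        """Central value used by the deterministic engine (the mean for all
        supported families)."""
        if self.kind == "point":
            return self.params[0]
        if self.kind in ("normal", "lognormal"):
            return self.params[0]
        if self.kind == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        if self.kind == "triangular":
            return sum(self.params) / 3.0
        raise RiskConfigError(self.kind)


def parse_dist(value) -> Dist:
    if isinstance(value, (int, float)):
        return Dist("point", (float(value),))
    if isinstance(value, Mapping):
        kind = value.get("dist", "point")
        if kind == "point":
            return Dist("point", (float(value["value"]),))
        if kind in ("normal", "lognormal"):
            return Dist(kind, (float(value["mean"]), float(value["sd"])))
        if kind == "uniform":
            return Dist(kind, (float(value["low"]), float(value["high"])))
        if kind == "triangular":
            return Dist(kind, (float(value["low"]), float(value["mode"]),
                               float(value["high"])))
    raise RiskConfigError(f"cannot parse distribution spec {value!r}")


@dataclass
class ExposureParameterSet:
    """Exposure parameters per receptor; every entry is a :class:`Dist`
    (degenerate ``point`` distributions for fixed values)."""

    receptors: dict[str, dict[str, Dist]]
    unit_conv: float = 1e-6

    def point_values(self, receptor: str) -> dict[str, float]:
        try:
            params = self.receptors[receptor]
        except KeyError:
            raise RiskConfigError(f"unknown receptor {receptor!r}") from None
        return {k: d.point for k, d in params.items()}


@dataclass
class ToxicityTable:
    """Per-element route-specific reference doses, slope factors and dermal
    absorption fractions; ``cr_pathways`` lists the routes included in the
    cancer-risk sum."""

    rfd: dict[str, dict[str, float]]
    sf: dict[str, dict[str, float]]
    abs_fraction: dict[str, float]
    cr_pathways: tuple[str, ...] = ("ingestion", "inhalation")

    def __post_init__(self) -> None:
        for el, routes in self.rfd.items():
            for route, v in routes.items():
                if v <= 0:
                    raise RiskConfigError(f"non-positive RfD for {el}/{route}")
        for el, routes in self.sf.items():
            for route, v in routes.items():
                if v < 0:
                    raise RiskConfigError(f"negative slope factor for {el}/{route}")


def _data_file(name: str):
    return importlib.resources.files("soilpte.data").joinpath(name)


def load_exposure(source: str | Path = "point") -> ExposureParameterSet:
    """Load an exposure parameterization.

    ``source`` may be ``"point"`` or ``"mc"`` for the packaged defaults, or a
    path to a YAML file of the same layout.
    """
    if source in ("point", "mc"):
        fh = _data_file(f"exposure_{source}.yaml").open("r")
    else:
        fh = open(source)
    with fh:
        raw = yaml.safe_load(fh)
    receptors = {}
    for rec in RECEPTORS:
        if rec not in raw:
            raise RiskConfigError(f"exposure config missing receptor {rec!r}")
        receptors[rec] = {k: parse_dist(v) for k, v in raw[rec].items()}
    eps = ExposureParameterSet(receptors, float(raw.get("unit_conv", 1e-6)))
    for rec in RECEPTORS:
        pv = eps.point_values(rec)
        for key in _POSITIVE_REQUIRED:
            if pv.get(key, 1.0) <= 0:
                raise RiskConfigError(f"{key} must be positive for {rec}")
    return eps


def load_toxicity(source: str | Path = "point") -> ToxicityTable:
    """Load a toxicity table (``"point"``, ``"mc"`` or a YAML path)."""
    if source in ("point", "mc"):
        fh = _data_file(f"toxicity_{source}.yaml").open("r")
    else:
        fh = open(source)
    with fh:
        raw = yaml.safe_load(fh)
    rfd, sf, absf = {}, {}, {}
    for el, entry in raw["elements"].items():
        rfd[el] = {k: float(v) for k, v in entry.get("rfd", {}).items()}
        sf[el] = {k: float(v) for k, v in entry.get("sf", {}).items()}
        absf[el] = float(entry.get("abs", 0.001))
    return ToxicityTable(rfd, sf, absf,
                         tuple(raw.get("cr_pathways", ["ingestion", "inhalation"])))


# ---------------------------------------------------------------------------
# dose arithmetic


def add_pathway(c, pathway: str, params: Mapping[str, float],
                risk: str = "noncarcinogenic", abs_fraction: float = 0.001,
                unit_conv: float = 1e-6):
    """Average daily dose (mg kg^-1 day^-1) for one route.

    ``c`` may be a scalar or an array; ``params`` maps parameter names to
    scalars or aligned arrays, so the same code serves the deterministic and
    the Monte-Carlo engines.
    """
    bw = np.asarray(params["BW"], float)
    ed = np.asarray(params["ED"], float)
    ef = np.asarray(params["EF"], float)
    if np.any(bw <= 0):
        raise RiskConfigError("non-positive body weight")
    if risk == "carcinogenic":
        at = np.asarray(params["AT_ca"], float)
        if np.any(at <= 0):
            raise RiskConfigError("non-positive averaging time")
    else:
        # AT = ED * 365; a zero exposure duration means zero dose, which the
        # ED factor in the numerator already produces, so substitute a
        # harmless denominator there.
        if np.any(ed < 0):
            raise RiskConfigError("negative exposure duration")
        at = np.where(ed > 0, ed * 365.0, 1.0)
    c = np.asarray(c, float)
    if pathway == "ingestion":
        return c * params["IngR"] * ef * ed * unit_conv / (bw * at)
    if pathway == "inhalation":
        pef = np.asarray(params["PEF"], float)
        if np.any(pef <= 0):
            raise RiskConfigError("non-positive PEF")
        return c * params["InhR"] * ef * ed / (pef * bw * at)
    if pathway == "dermal":
        return (c * params["SA"] * params["AF"] * abs_fraction
                * ef * ed * unit_conv / (bw * at))
    raise RiskConfigError(f"unknown pathway {pathway!r}")


def hazard_quotient(add, rfd: float):
    if rfd <= 0:
        raise RiskConfigError("RfD must be positive")
    return np.asarray(add, float) / rfd


def hazard_index(hqs):
    hqs = list(hqs)
    if not hqs:
        return 0.0
    return np.sum(np.asarray(hqs, dtype=object), axis=0)


def cancer_risk(add, sf: float):
    if sf < 0:
        raise RiskConfigError("slope factor must be non-negative")
    return np.asarray(add, float) * sf


def total_cancer_risk(crs):
    crs = list(crs)
    if not crs:
        return 0.0
    return np.sum(np.asarray(crs, dtype=object), axis=0)


# ---------------------------------------------------------------------------
# result container


@dataclass
class RiskResult:
    """Risk assessment output for one receptor.

    ``add`` maps element -> pathway -> non-carcinogenic ADD; ``hq``/``cr``
    are per-element totals over routes; ``hi``/``tcr`` their sums.  After a
    Monte-Carlo run, ``summary`` holds mean/median/p5/p95 rows for HI, TCR
    and the per-element HQ and CR.
    """

    receptor: str
    add: dict[str, dict[str, float]]
    hq: dict[str, float]
    hi: float
    cr: dict[str, float]
    tcr: float
    summary: dict[str, dict[str, float]] = field(default_factory=dict)
    n_iter: int = 0
    seed: int | None = None


def _risk_arrays(conc: Mapping[str, float], params: Mapping[str, np.ndarray],
                 toxicity: ToxicityTable, unit_conv: float):
    """HQ and CR per element (scalar or per-draw arrays)."""
    hq: dict[str, np.ndarray] = {}
    cr: dict[str, np.ndarray] = {}
    add_nc: dict[str, dict[str, np.ndarray]] = {}
    for el, c in conc.items():
        if el not in toxicity.rfd:
            raise RiskConfigError(f"no reference doses configured for {el}")
        absf = toxicity.abs_fraction.get(el, 0.001)
        add_nc[el] = {}
        hq_el = 0.0
        for pw in PATHWAYS:
            rfd = toxicity.rfd[el].get(pw)
            dose = add_pathway(c, pw, params, "noncarcinogenic", absf, unit_conv)
            add_nc[el][pw] = dose
            if rfd is not None:
                hq_el = hq_el + dose / rfd
        hq[el] = hq_el
        sfs = toxicity.sf.get(el, {})
        if sfs:
            cr_el = 0.0
            for pw in toxicity.cr_pathways:
                sf = sfs.get(pw)
                if sf is None:
                    continue
                dose = add_pathway(c, pw, params, "carcinogenic", absf, unit_conv)
                cr_el = cr_el + dose * sf
            cr[el] = cr_el
    return hq, cr, add_nc


def deterministic_risk(conc: Mapping[str, float], exposure: ExposureParameterSet,
                       toxicity: ToxicityTable, receptor: str) -> RiskResult:
    """Point-value risk pipeline over all elements and three pathways."""
    params = exposure.point_values(receptor)
    hq, cr, add_nc = _risk_arrays(conc, params, toxicity, exposure.unit_conv)
    hq_f = {el: float(v) for el, v in hq.items()}
    cr_f = {el: float(v) for el, v in cr.items()}
    return RiskResult(
        receptor=receptor,
        add={el: {pw: float(d) for pw, d in row.items()} for el, row in add_nc.items()},
        hq=hq_f, hi=float(sum(hq_f.values())),
        cr=cr_f, tcr=float(sum(cr_f.values())),
    )


def monte_carlo_risk(conc: Mapping[str, float], exposure: ExposureParameterSet,
                     toxicity: ToxicityTable, receptor: str,
                     n_iter: int = 10_000, seed: int | None = None,
                     percentiles: tuple[float, float] = (5.0, 95.0)) -> RiskResult:
    """Monte-Carlo risk assessment.

    Exposure parameters are drawn per iteration; concentrations are held at
    their central values.  Summaries report the mean, median and the
    requested lower/upper percentiles (5th/95th by default).
    """
    if n_iter < 1:
        raise RiskConfigError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    dists = exposure.receptors[receptor]
    params = {k: d.sample(rng, n_iter) for k, d in dists.items()}
    hq, cr, _ = _risk_arrays(conc, params, toxicity, exposure.unit_conv)
    hi = np.sum(np.stack([np.broadcast_to(v, n_iter) for v in hq.values()]), axis=0)
    if cr:
        tcr = np.sum(np.stack([np.broadcast_to(v, n_iter) for v in cr.values()]), axis=0)
    else:
        tcr = np.zeros(n_iter)

    lo, hi_q = percentiles

    def stats(a: np.ndarray) -> dict[str, float]:
        return {
            "mean": float(np.mean(a)),
            "median": float(np.median(a)),
            f"p{lo:g}": float(np.percentile(a, lo)),
            f"p{hi_q:g}": float(np.percentile(a, hi_q)),
        }

    summary = {"HI": stats(hi), "TCR": stats(tcr)}
    for el, v in hq.items():
        summary[f"HQ[{el}]"] = stats(np.broadcast_to(v, n_iter))
    for el, v in cr.items():
        summary[f"CR[{el}]"] = stats(np.broadcast_to(v, n_iter))

    hq_mean = {el: float(np.mean(v)) for el, v in hq.items()}
    cr_mean = {el: float(np.mean(v)) for el, v in cr.items()}
    return RiskResult(
        receptor=receptor, add={},
        hq=hq_mean, hi=float(np.mean(hi)),
        cr=cr_mean, tcr=float(np.mean(tcr)),
        summary=summary, n_iter=n_iter, seed=seed,
    )


def risk_shares(result: RiskResult) -> tuple[dict[str, float], dict[str, float]]:
    """Per-element percentage share of HI and of TCR (each sums to 100)."""
    if result.hi <= 0:
        raise RiskConfigError("HI is zero; shares undefined")
    hi_shares = {el: 100.0 * v / result.hi for el, v in result.hq.items()}
    tcr_shares: dict[str, float] = {}
    if result.cr:
        if result.tcr <= 0:
            raise RiskConfigError("TCR is zero; shares undefined")
        tcr_shares = {el: 100.0 * v / result.tcr for el, v in result.cr.items()}
    return hi_shares, tcr_shares


def grand_mean_concentrations(table) -> dict[str, float]:
    """Study-area mean concentration per element from a land-use mean table
    (balanced design: the grand mean is the mean of land-use means)."""
    return {el: float(table[el].mean()) for el in ELEMENTS}
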
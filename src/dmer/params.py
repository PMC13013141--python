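"""Parameter-set container and configuration I/O.

The full joint model is parameterized by shared structural values (turnover
rate, normalizing maximum effect, placebo factor), per-endpoint fixed effects
(baseline, Emax, residual SD), interindividual variances with eta sharing,
covariate effects of muscle-predominant disease, and PK/simulation settings.
The shipped default configuration holds the final-model typical values; any
compatible YAML file can replace it.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .exposure import PKParams
from .model_core import EndpointSpec, SharedParams

ENDPOINT_ORDER = [
    "cdasi_d", "cdasi_a", "sf36_pfd", "sf36_mcs", "phga", "ptga",
    "enzyme", "exga", "haq", "mmt8", "tis_phga",
]

__all__ = ["ParameterSet", "load_parameter_config", "default_parameters",
           "ENDPOINT_ORDER"]


@dataclass
class CovariateEffect:
    """Percent change applied to a parameter for one covariate level."""

    covariate: str
    target: str              # "baseline" or "e_plac"
    percent: float
    endpoint: str | None = None

    @property
    def factor(self) -> float:
        return 1.0 + self.percent / 100.0


@dataclass
class ParameterSet:
    """All fixed effects, variances, sharing scalars and settings."""

    shared: SharedParams
    endpoints: dict[str, EndpointSpec]
    iiv_emax_norm: float
    iiv_e_plac: float
    block_correlation: float
    covariates: list[CovariateEffect]
    pk: PKParams
    infusion_duration_hr: float = 1.0
    mmt8_spdm_shift: float = 0.946
    mmt8_spdm_var_shrink: float = 0.25
    uln_catalogue: list[float] = field(default_factory=lambda: [40.0, 200.0, 250.0])
    source_checksum: str = ""

    def __post_init__(self):
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block correlation must lie in [0, 1)")
        if self.iiv_emax_norm < 0 or self.iiv_e_plac < 0:
            raise ValueError("IIV variances must be non-negative")
        for spec in self.endpoints.values():
            if spec.eta_source is not None:
                src = self.endpoints.get(spec.eta_source)
                if src is None or src.eta_source is not None:
                    raise ValueError(
                        f"{spec.name}: eta_source must name a block endpoint")

    @property
    def block_endpoints(self) -> list[str]:
        """Endpoints whose baseline eta is drawn in the correlated block."""
        return [n for n, s in self.endpoints.items() if s.eta_source is None]

    def subset(self, names) -> "ParameterSet":
        """Restricted parameter set over a sub-panel of endpoints.

        Endpoints whose eta donor is outside the panel keep the donor in the
        eta block (unobserved donors are still drawn so sharing is preserved).
        """
        keep = set(names)
        for n in names:
            src = self.endpoints[n].eta_source
            if src is not None:
                keep.add(src)
        out = copy.deepcopy(self)
        out.endpoints = {n: copy.deepcopy(self.endpoints[n])
                         for n in ENDPOINT_ORDER if n in keep}
        out.covariates = [c for c in self.covariates
                          if c.endpoint is None or c.endpoint in keep]
        return out

    def to_dict(self) -> dict:
        eps = {}
        for name, s in self.endpoints.items():
            d = {"label": s.label, "range": [s.range_lo, s.range_hi],
                 "direction": s.improvement_direction, "baseline": s.baseline,
                 "emax": s.emax, "ruv_sd": s.ruv_sd}
            if s.emax_fixed:
                d["emax_fixed"] = True
            if s.is_enzyme:
                d["is_enzyme"] = True
            if s.eta_source is None:
                d["iiv_baseline"] = s.iiv_baseline
            else:
                d["eta_source"] = s.eta_source
                d["eta_scalar"] = s.eta_scalar
                if s.eta_own_var is not None:
                    d["eta_own_var"] = s.eta_own_var
            eps[name] = d
        return {
            "shared": {"kout": self.shared.k_out,
                       "emax_norm": self.shared.emax_norm,
                       "e_plac": self.shared.e_plac},
            "iiv": {"emax_norm": self.iiv_emax_norm,
                    "e_plac": self.iiv_e_plac,
                    "block_correlation": self.block_correlation},
            "endpoints": eps,
            "covariates": [{"covariate": c.covariate, "endpoint": c.endpoint,
                            "target": c.target, "percent": c.percent}
                           for c in self.covariates],
            "pk": {"CL": self.pk.CL, "V1": self.pk.V1, "V2": self.pk.V2,
                   "Q": self.pk.Q, "K_SS": self.pk.K_SS,
                   "infusion_duration_hr": self.infusion_duration_hr},
            "simulation": {"mmt8_spdm_shift": self.mmt8_spdm_shift,
                           "mmt8_spdm_var_shrink": self.mmt8_spdm_var_shrink,
                           "uln_catalogue": list(self.uln_catalogue)},
        }

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _parse(doc: dict, checksum: str = "") -> ParameterSet:
    try:
        sh = doc["shared"]
        shared = SharedParams(k_out=float(sh["kout"]),
                              emax_norm=float(sh["emax_norm"]),
                              e_plac=float(sh.get("e_plac", 1.0)))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"invalid shared-parameter block: {exc}") from exc

    endpoints = {}
    for name, d in doc["endpoints"].items():
        lo, hi = d["range"]
        try:
            endpoints[name] = EndpointSpec(
                name=name, label=d.get("label", name),
                range_lo=float(lo), range_hi=float(hi),
                improvement_direction=d["direction"],
                emax=float(d["emax"]), baseline=float(d["baseline"]),
                ruv_sd=float(d["ruv_sd"]),
                emax_fixed=bool(d.get("emax_fixed", False)),
                is_enzyme=bool(d.get("is_enzyme", False)),
                iiv_baseline=float(d.get("iiv_baseline", 0.0)),
                eta_source=d.get("eta_source"),
                eta_scalar=float(d.get("eta_scalar", 1.0)),
                eta_own_var=(None if d.get("eta_own_var") is None
                             else float(d["eta_own_var"])),
            )
        except ValueError as exc:
            raise ValueError(f"endpoint '{name}': {exc}") from exc

    iiv = doc.get("iiv", {})
    covs = [CovariateEffect(covariate=c["covariate"], target=c["target"],
                            percent=float(c["percent"]),
                            endpoint=c.get("endpoint"))
            for c in doc.get("covariates", [])]
    for c in covs:
        if c.target == "baseline" and c.endpoint not in endpoints:
            raise ValueError(f"covariate on unknown endpoint '{c.endpoint}'")

    pkd = doc.get("pk", {})
    pk = PKParams(CL=float(pkd.get("CL", 1.6)), V1=float(pkd.get("V1", 3.5)),
                  V2=float(pkd.get("V2", 2.6)), Q=float(pkd.get("Q", 4.9)),
                  K_SS=float(pkd.get("K_SS", 1.0)))
    sim = doc.get("simulation", {})
    return ParameterSet(
        shared=shared, endpoints=endpoints,
        iiv_emax_norm=float(iiv.get("emax_norm", 0.0)),
        iiv_e_plac=float(iiv.get("e_plac", 0.0)),
        block_correlation=float(iiv.get("block_correlation", 0.0)),
        covariates=covs, pk=pk,
        infusion_duration_hr=float(pkd.get("infusion_duration_hr", 1.0)),
        mmt8_spdm_shift=float(sim.get("mmt8_spdm_shift", 0.946)),
        mmt8_spdm_var_shrink=float(sim.get("mmt8_spdm_var_shrink", 0.25)),
        uln_catalogue=[float(u) for u in sim.get("uln_catalogue",
                                                 [40.0, 200.0, 250.0])],
        source_checksum=checksum,
    )


def load_parameter_config(path) -> ParameterSet:
    """Load and validate a parameter configuration file (YAML)."""
    with open(path) as fh:
        text = fh.read()
    doc = yaml.safe_load(text)
    return _parse(doc, hashlib.sha256(text.encode()).hexdigest()[:12])


def default_parameters() -> ParameterSet:
    """The shipped default parameter set (final-model typical values)."""
    text = resources.files("dmer.data").joinpath("parameters.yaml").read_text()
    return _parse(yaml.safe_load(text),
                  hashlib.sha256(text.encode()).hexdigest()[:12])
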
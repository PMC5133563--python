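"""Run configuration: one object holding every tunable, YAML round-trip.

Defaults are the published protocol values: window xi=6/eta=9 with X padding,
50 mRMR-selected features, RBF gamma 0.0125, decision threshold theta 0.5.
Every command logs a fingerprint of its fully resolved configuration so runs
are attributable and reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .evaluation import CVPlan
from .model import MRMRConfig, SVMConfig
from .mrmr import DiscretizationScheme
from .windows import WindowConfig

log = logging.getLogger("malsite")


@dataclass(frozen=True)
class RedundancyConfig:
    enabled: bool = True
    threshold: float = 0.4
    scope: str = "all"  # or "within-class"


@dataclass(frozen=True)
class RunConfig:
    window: WindowConfig = field(default_factory=WindowConfig)
    redundancy: RedundancyConfig = field(default_factory=RedundancyConfig)
    mrmr: MRMRConfig = field(default_factory=MRMRConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    cv: CVPlan = field(default_factory=CVPlan)
    property_table_path: str | None = None
    binary_kgrams: bool = False
    scale: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        s = str(source)
        text = Path(s).read_text() if ("\n" not in s and Path(s).exists()) else s
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs: dict = {}
        if "window" in data:
            kwargs["window"] = WindowConfig(**data["window"])
        if "redundancy" in data:
            kwargs["redundancy"] = RedundancyConfig(**data["redundancy"])
        if "mrmr" in data:
            m = dict(data["mrmr"])
            if "discretization" in m:
                m["discretization"] = DiscretizationScheme(**m["discretization"])
            kwargs["mrmr"] = MRMRConfig(**m)
        if "svm" in data:
            kwargs["svm"] = SVMConfig(**data["svm"])
        if "cv" in data:
            kwargs["cv"] = CVPlan(**data["cv"])
        for key in ("property_table_path", "binary_kgrams", "scale", "seed"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def log_resolved(self) -> None:
        log.info(
            "resolved config (fingerprint %s): xi=%d eta=%d pad=%s | mRMR n=%d %s | "
            "SVM gamma=%g C=%g theta=%g | CV %s k=%d repeats=%d | seed=%d",
            self.fingerprint(),
            self.window.xi, self.window.eta, self.window.pad_char,
            self.mrmr.n_features, self.mrmr.scheme,
            self.svm.gamma, self.svm.C, self.svm.theta,
            self.cv.scheme, self.cv.k, self.cv.repeats,
            self.seed,
        )


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
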
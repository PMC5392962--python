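"""Run configuration: every tunable of the imaging chain and the statistics
layer, serialisable to YAML and hashable for provenance."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    FCM: fuzzifier ``m`` (> 1), centroid-shift tolerance, iteration cap,
    cluster counts for the outer (air separation, default 4) and inner
    (tissue classification, default 3) stages; an operator may override the
    cluster counts when a segmentation is unsatisfactory.

    Geometry: gradient-trace search half-window in columns, and the CC
    lateral-side convention per laterality (chest-left/superior-top images).

    Combination: ``quarter_sum`` (default) or ``half_sum``.

    Statistics: the normal quantile for CIs and the multiple-comparison
    method for pairwise proportion tests.
    """

    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    clusters_outer: int = 4
    clusters_inner: int = 3
    normalize_intensities: bool = False
    trace_window: int = 5
    cc_lateral_side: dict = field(
        default_factory=lambda: {"L": "top", "R": "bottom"})
    combination_mode: str = "quarter_sum"
    ci_z: float = 1.959963984540054
    adjustment_method: str = "bonferroni"
    seed: int = 0
    outdir: str = "mammoquad_out"

    def validate(self) -> None:
        if not self.fcm_m > 1:
            raise ParameterError("fcm_m must be > 1")
        if self.fcm_tol <= 0 or self.fcm_max_iter < 1:
            raise ParameterError("fcm_tol must be > 0, fcm_max_iter >= 1")
        if self.clusters_outer < 2 or self.clusters_inner < 2:
            raise ParameterError("cluster counts must be >= 2")
        if self.trace_window < 1:
            raise ParameterError("trace_window must be >= 1")
        if self.combination_mode not in ("quarter_sum", "half_sum"):
            raise ParameterError("combination_mode must be quarter_sum|half_sum")
        if self.ci_z <= 0:
            raise ParameterError("ci_z must be > 0")
        if set(self.cc_lateral_side) != {"L", "R"} or \
                not set(self.cc_lateral_side.values()) <= {"top", "bottom"}:
            raise ParameterError("cc_lateral_side must map L/R to top/bottom")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "RunConfig":
        p = Path(path_or_text)
        text = p.read_text() if p.exists() else str(path_or_text)
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @property
    def hash(self) -> str:
        """Short stable digest of the canonical YAML serialisation."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
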
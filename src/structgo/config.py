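"""Run configuration shared by the command-line surface."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import yaml

from .errors import ValidationError
from .io import DEFAULT_EVIDENCE_EXCLUSIONS

logger = logging.getLogger(__name__)


@dataclass
class ViewSpec:
    """One data view: a name and its kernel/feature source files.

    A source path prefixed with ``kernel:`` is read as a precomputed kernel
    TSV; otherwise it is a feature TSV turned into a linear kernel.
    """

    name: str
    sources: list[str]


@dataclass
class RunConfig:
    namespace: str = "MF"
    views: list[ViewSpec] = field(default_factory=list)
    mode: str = "single"  # single | multiview | chain
    c_over_n: float = 1.0
    tolerance: float = 1e-4
    folds: int = 5
    seed: int = 0
    evidence_exclusions: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_EVIDENCE_EXCLUSIONS)
    )

    def validate(self) -> None:
        if self.mode not in ("single", "multiview", "chain"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode in ("multiview", "chain") and len(self.views) < 2:
            raise ValidationError(f"mode {self.mode!r} requires ≥2 views")
        if self.c_over_n <= 0 or self.tolerance <= 0:
            raise ValidationError("c_over_n and tolerance must be positive")
        for view in self.views:
            for src in view.sources:
                path = src.removeprefix("kernel:")
                if not os.path.exists(path):
                    raise ValidationError(
                        f"view {view.name!r}: source file {path!r} not found"
                    )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        views = [ViewSpec(**v) for v in data.pop("views", [])]
        return cls(views=views, **data)
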
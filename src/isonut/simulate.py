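"""Class-conditional Gaussian simulator for multi-isotopic hazelnut data.

Only per-origin marker means and standard deviations of the real study are
public, so each (origin, harvest-year) cell is drawn from a multivariate
Gaussian whose mean is the origin mean plus an optional additive year shift
and whose covariance is ``diag(sd) @ C @ diag(sd)`` for a configurable
correlation matrix ``C`` (identity by default).  This reproduces the
published marginal structure; it deliberately does not model the real
within-class covariance, which is unpublished.

Reproducibility contract: one root seed; every (origin, year) cell draws
from its own deterministic substream, so changing one cell's count never
perturbs the samples of any other cell.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .data import MARKER_NAMES, IsotopeDataset


class ConfigError(ValueError):
    """Invalid generator configuration."""


# Per-origin marker means and SDs (per-mil) of the published four-origin
# hazelnut study, marker order = MARKER_NAMES.
_STUDY_MEANS = {
    "CHL": [23.7, -29.9, -31.0, -28.4, -30.5, -179.0, -191.3, -215.3],
    "ESP": [23.6, -29.9, -30.8, -28.4, -30.5, -163.0, -174.8, -199.5],
    "GEO": [19.8, -31.8, -32.8, -30.3, -32.7, -186.6, -197.5, -219.4],
    "ITA": [24.8, -29.9, -31.3, -28.3, -30.5, -166.5, -179.4, -200.7],
}
_STUDY_SDS = {
    "CHL": [0.7, 0.7, 1.2, 0.6, 0.7, 6.8, 5.3, 5.8],
    "ESP": [0.8, 0.5, 1.1, 0.5, 0.7, 8.2, 5.4, 6.7],
    "GEO": [0.5, 1.2, 1.1, 1.3, 1.6, 6.9, 5.3, 5.0],
    "ITA": [0.8, 0.6, 1.2, 0.6, 0.9, 8.2, 6.9, 7.7],
}
# Samples per origin and harvest year in the real sampling design (n = 207).
_STUDY_DESIGN = {
    "CHL": {2019: 20, 2020: 20},
    "ESP": {2019: 23, 2020: 23, 2021: 23, 2022: 22},
    "GEO": {2021: 20, 2022: 20},
    "ITA": {2019: 12, 2020: 12, 2021: 12},
}


@dataclass
class GeneratorConfig:
    """Parameters of the class-conditional Gaussian generator.

    Attributes
    ----------
    means, sds
        Per-origin 8-vectors (per-mil), marker order = ``MARKER_NAMES``.
    correlation
        ``None`` for independent markers (diagonal covariance), or a shared
        8x8 correlation matrix applied to every origin.
    year_design
        Per-origin mapping ``{year: sample count}``.
    year_effects
        Optional additive mean shifts per (origin, year): 8-vectors added to
        the origin mean; defaults to zero everywhere.
    seed
        Root seed; ``generate`` is a pure function of the config.
    """

    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    year_design: dict[str, dict[int, int]]
    correlation: np.ndarray | None = None
    year_effects: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = {o: np.asarray(v, dtype=float) for o, v in self.means.items()}
        self.sds = {o: np.asarray(v, dtype=float) for o, v in self.sds.items()}
        self.year_effects = {
            (o, int(y)): np.asarray(v, dtype=float)
            for (o, y), v in self.year_effects.items()
        }
        if self.correlation is not None:
            self.correlation = np.asarray(self.correlation, dtype=float)
        self.validate()

    def validate(self) -> None:
        p = len(MARKER_NAMES)
        if set(self.means) != set(self.sds) or set(self.means) != set(
            self.year_design
        ):
            raise ConfigError("means, sds and year_design must share origins")
        for origin in self.means:
            if self.means[origin].shape != (p,) or self.sds[origin].shape != (p,):
                raise ConfigError(f"origin {origin!r}: need {p}-vectors")
            if np.any(self.sds[origin] <= 0):
                raise ConfigError(f"origin {origin!r}: all SDs must be > 0")
            counts = self.year_design[origin]
            if any(c < 0 for c in counts.values()):
                raise ConfigError(f"origin {origin!r}: negative cell count")
            if sum(counts.values()) <= 0:
                raise ConfigError(f"origin {origin!r}: no samples in design")
        if self.correlation is not None:
            C = self.correlation
            if C.shape != (p, p):
                raise ConfigError("correlation must be 8x8")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ConfigError("correlation must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ConfigError("correlation must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ConfigError("correlation must be positive semi-definite")

    @property
    def n_total(self) -> int:
        return sum(sum(d.values()) for d in self.year_design.values())

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "seed": int(self.seed),
            "markers": list(MARKER_NAMES),
            "origins": {
                o: {
                    "means": [float(v) for v in self.means[o]],
                    "sds": [float(v) for v in self.sds[o]],
                    "year_design": {
                        int(y): int(c) for y, c in self.year_design[o].items()
                    },
                }
                for o in sorted(self.means)
            },
            "correlation": None
            if self.correlation is None
            else [[float(v) for v in row] for row in self.correlation],
            "year_effects": {
                f"{o}:{y}": [float(v) for v in eff]
                for (o, y), eff in sorted(self.year_effects.items())
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            means={o: d["means"] for o, d in doc["origins"].items()},
            sds={o: d["sds"] for o, d in doc["origins"].items()},
            year_design={
                o: {int(y): int(c) for y, c in d["year_design"].items()}
                for o, d in doc["origins"].items()
            },
            correlation=doc.get("correlation"),
            year_effects={
                (key.split(":")[0], int(key.split(":")[1])): v
                for key, v in (doc.get("year_effects") or {}).items()
            },
            seed=int(doc.get("seed", 0)),
        )


def default_study_config(seed: int = 0) -> GeneratorConfig:
    """The study-design configuration: published per-origin means/SDs, the
    real per-year sampling counts (n = 207 total), independent markers and
    zero year effects."""
    return GeneratorConfig(
        means={o: list(v) for o, v in _STUDY_MEANS.items()},
        sds={o: list(v) for o, v in _STUDY_SDS.items()},
        year_design={o: dict(d) for o, d in _STUDY_DESIGN.items()},
        correlation=None,
        year_effects={},
        seed=seed,
    )


def _cell_rng(seed: int, origin: str, year: int) -> np.random.Generator:
    # deterministic substream per (origin, year) cell
    tag = zlib.crc32(origin.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, int(year)])
    )


def _covariance_factor(sds: np.ndarray, C: np.ndarray | None) -> np.ndarray | None:
    """Lower factor L with L L' = diag(sd) C diag(sd); None for diagonal."""
    if C is None:
        return None
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        raise ConfigError("correlation must be positive semi-definite")
    L = V * np.sqrt(np.clip(w, 0.0, None))
    return sds[:, None] * L


def generate(config: GeneratorConfig, seed: int | None = None) -> IsotopeDataset:
    """Draw a dataset from the configured class-conditional Gaussian.

    A pure function of the config (including its seed); *seed* overrides
    ``config.seed`` when given.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    root = config.seed
    ids: list[str] = []
    origins: list[str] = []
    years: list[int] = []
    blocks: list[np.ndarray] = []
    for origin in sorted(config.means):
        L = _covariance_factor(config.sds[origin], config.correlation)
        for year in sorted(config.year_design[origin]):
            count = config.year_design[origin][year]
            if count == 0:
                continue
            mu = config.means[origin] + config.year_effects.get(
                (origin, year), 0.0
            )
            rng = _cell_rng(root, origin, year)
            Z = rng.standard_normal((count, len(MARKER_NAMES)))
            if L is None:
                block = mu + Z * config.sds[origin]
            else:
                block = mu + Z @ L.T
            blocks.append(block)
            for i in range(count):
                ids.append(f"{origin}_{year}_{i + 1:03d}")
                origins.append(origin)
                years.append(year)
    X = np.vstack(blocks) if blocks else np.empty((0, len(MARKER_NAMES)))
    return IsotopeDataset(
        np.array(ids, dtype=object),
        np.array(origins, dtype=object),
        np.array(years, dtype=int),
        X,
    )
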
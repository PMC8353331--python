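"""Run configuration: one YAML file plus CLI overrides.

Precedence is CLI > file > defaults.  Paths are resolved relative to the
config file's directory; :meth:`RunConfig.validate` checks that every
referenced path exists and that parameters are in range, raising
:class:`ConfigError` (the CLI maps this to exit code 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    # inputs
    sample_sheet: Path | None = None
    vcf_dir: Path | None = None
    seg_dir: Path | None = None
    marker_matrix: Path | None = None  # alternative to vcf_dir/seg_dir
    reference_fasta: Path | None = None
    signature_tsv: Path | None = None  # None -> packaged synthetic reference
    exon_bed: Path | None = None
    msi_dir: Path | None = None
    gene_panel: tuple = ()
    # parameters
    alpha: float = 0.05
    max_combo_size: int = 3
    target_size_mb: float = 50.0
    ploidy: float = 2.0
    msi_min_depth: int = 20
    msi_shift_threshold: float = 0.3
    seed: int = 0
    # output
    outdir: Path = Path("platmark_out")

    def validate(self, require: tuple = ()) -> "RunConfig":
        """Check ranges and (for the given required inputs) path existence."""
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.max_combo_size < 1:
            raise ConfigError(f"max_combo_size must be >= 1, got {self.max_combo_size}")
        if self.target_size_mb <= 0:
            raise ConfigError(f"target_size_mb must be > 0, got {self.target_size_mb}")
        if self.ploidy <= 0:
            raise ConfigError(f"ploidy must be > 0, got {self.ploidy}")
        if not (0.0 <= self.msi_shift_threshold <= 1.0):
            raise ConfigError(
                f"msi_shift_threshold must be in [0, 1], got {self.msi_shift_threshold}"
            )
        for name in require:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config field {name!r} is required for this command")
            if isinstance(value, Path) and not value.exists():
                raise ConfigError(f"{name}: path does not exist: {value}")
        return self

    def with_overrides(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        path_fields = {
            f.name for f in fields(self) if "Path" in str(f.type)
        }
        for k, v in list(clean.items()):
            if k in path_fields:
                clean[k] = Path(v)
        return replace(self, **clean)


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML config file (or return defaults when ``path`` is None)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    base = path.parent
    cfg = RunConfig()
    for key, value in raw.items():
        if value is None:
            continue
        current = getattr(cfg, key)
        if key == "gene_panel":
            value = tuple(value)
        elif isinstance(current, Path) or (current is None and key != "gene_panel"):
            value = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
        setattr(cfg, key, value)
    return cfg
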
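"""Run configuration and results-table I/O."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

__all__ = ["RunConfig", "read_results", "write_results"]


@dataclass
class RunConfig:
    """Resolved settings for a pipeline run; serializes round-trip
    stable to YAML and is written alongside every run's outputs."""

    bed_prefix: str = ""
    phenotype: str = ""
    kinship: str = ""
    out: str = ""
    method: str = "pc_lmem"
    n_pcs: int = 3
    d_rho: float = 0.5
    mode: str = "approx"
    call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    relatedness_threshold: float = 0.125
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**(data or {}))

    def override(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        for k, v in kwargs.items():
            if v is not None:
                if k not in data:
                    raise KeyError(f"unknown config key {k!r}")
                data[k] = v
        return RunConfig(**data)


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "converged" in df.columns:
        df["converged"] = df["converged"].astype(bool)
    return df
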
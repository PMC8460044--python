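"""Pipeline configuration: one flat record of every tunable, with strict parsing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .simulate import DEFAULT_CONSERVATIVE_PROBS


@dataclass
class PipelineConfig:
    """Defaults equal the values stated in each stage's module documentation."""

    # synthetic cohort
    seed: int = 1
    n_scaffolds: int = 2
    scaffold_length: int = 150_000
    gene_density: float = 0.4
    n_circles: int = 30
    n_with_him: int = 19
    circle_len_range: tuple[int, int] = (700, 1500)
    spacer_len_range: tuple[int, int] = (39, 72)
    events_per_circle: int = 48
    conservative_probs: tuple[float, ...] = DEFAULT_CONSERVATIVE_PROBS
    coverage: float = 8.0
    read_len: int = 150
    error_rate: float = 0.002
    include_episomes: bool = True
    # chimera detection
    min_aln_len: int = 28
    evalue_max: float = 1e-5
    max_overlap: int = 10
    max_gap: int = 10
    seed_k: int = 13
    # breakpoint profiling
    cluster_tol: int = 3
    cbc_threshold: float = 0.35
    min_support: int = 20
    # HIM discovery
    search_window: int = 30
    # host landscape
    window_size: int = 100_000
    flank: int = 20
    merge_tol: int = 3
    # integration index
    onset_threshold_pct: float = 25.0
    bins_h: tuple[float, float] = (0.5, 1.0)
    ct_noise_sd: float = 0.15
    ct_replicates: int = 3
    baseline_ct: float = 20.0
    efficiency: float = 1.0
    plateau: float = 0.8

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = sorted(set(data) - set(known))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        coerced = {}
        for key, value in data.items():
            if isinstance(value, list):
                value = tuple(value)
            coerced[key] = value
        return cls(**coerced)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def write(self, path: str) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.to_dict().items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
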
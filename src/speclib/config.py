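"""Build configuration: every threshold and tolerance in one place.

Defaults are the library's standard operating point: 1% FDR at the PSM,
local-precursor (window 500, per peptide length) and picked-protein
levels; candidate caps of 100 globally and 20 per dataset; quality gates
of 40% explained fragment intensity and 50 ppm precursor mass error;
0.1 Da fragment tolerance; SILAC concordance gates of 0.6 aligned cosine,
0.5 explained intensity in both members and a 1-minute co-elution window;
greedy proteotypic selection to 90% coverage capped at 20 precursors.

Every run writes a frozen config snapshot next to its outputs so a
library can always be tied back to the exact parameters that built it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class BuildConfig:
    psm_fdr: float = 0.01
    local_fdr: float = 0.01
    local_fdr_window: int = 500
    window_mode: str = "trailing"  # or "centered"
    protein_fdr: float = 0.01
    top_candidates: int = 100
    per_dataset_cap: int = 20
    explained_intensity_min: float = 0.40
    precursor_ppm_max: float = 50.0
    fragment_tolerance_da: float = 0.1
    allow_c13: bool = True
    il_equivalent: bool = False
    min_novel_peptide_length: int = 9
    proteotypic_coverage: float = 0.90
    proteotypic_cap: int = 20
    silac_min_cosine: float = 0.6
    silac_min_explained: float = 0.5
    silac_max_rt_delta_min: float = 1.0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "BuildConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "BuildConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
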
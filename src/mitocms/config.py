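"""Schema-validated pipeline configuration (YAML-facing, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .simulate import ChimeraPlan, SimConfig, TmOrfPlan


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    genome_length: int = 100_000
    gc_target: float = 0.446
    n_snps: int = 58
    n_ncrna_snps: int = 4
    n_small_indels: int = 18
    indel_insertion_fraction: float = 1 / 3
    sv_plan: list[tuple[str, int]] | None = None
    repeat_plan: list[tuple[int, str, int]] | None = None
    chimera: bool = True
    chimera_gap5: int = 20
    chimera_gap3: int = 18
    tm_orf: bool = True
    extra_unique_orf_aa: list[int] = [117, 133, 149]

    def to_sim_config(self, seed: int) -> SimConfig:
        kwargs = dict(
            genome_length=self.genome_length,
            gc_target=self.gc_target,
            n_snps=self.n_snps,
            n_ncrna_snps=self.n_ncrna_snps,
            n_small_indels=self.n_small_indels,
            indel_insertion_fraction=self.indel_insertion_fraction,
            extra_unique_orf_aa=list(self.extra_unique_orf_aa),
            chimera_plan=ChimeraPlan(gap5=self.chimera_gap5, gap3=self.chimera_gap3)
            if self.chimera
            else None,
            tm_orf_plan=TmOrfPlan() if self.tm_orf else None,
            seed=seed,
        )
        if self.sv_plan is not None:
            kwargs["sv_plan"] = [tuple(x) for x in self.sv_plan]
        if self.repeat_plan is not None:
            kwargs["repeat_plan"] = [tuple(x) for x in self.repeat_plan]
        return SimConfig(**kwargs)


class AnnotateSection(_Section):
    min_aa: int = 100
    min_coverage: float = 0.40
    min_identity: float = 50.0


class RepeatSection(_Section):
    min_len: int = 30
    bin_width: int = 5


class AlignSection(_Section):
    min_anchor: int = 20
    max_gap: int = 50_000
    min_chain_bp: int = 500
    gap_diff_cost: float = 0.5
    band: int = 2000
    sv_min: int = 50
    complex_identity: float = 0.70
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0


class VariantSection(_Section):
    flank: int = 100
    gap_mask: int = 5
    max_indel_len: int = 10


class SyntenySection(_Section):
    min_sv_size: int = 50
    homology_min_identity: float = 0.90


class TmSection(_Section):
    window: int = 19
    threshold: float = 1.6
    min_len: int = 15
    max_len: int = 35
    min_gap: int = 5
    chimera_max_gap: int = 100


class ScreenSection(_Section):
    min_identity: float = 0.90
    min_coverage: float = 0.90


class MarkerSection(_Section):
    target_len: int = 3000
    tolerance: float = 0.20
    primer_min: int = 18
    primer_max: int = 25
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_max_diff: float = 5.0
    max_amplicon: int = 6000
    max_mismatch: int = 0
    panel_lines: int = 17
    panel_fraction_sterile: float = 4 / 17


class PipelineConfig(_Section):
    seed: int = 1
    simulate: SimulateSection = SimulateSection()
    annotate: AnnotateSection = AnnotateSection()
    repeats: RepeatSection = RepeatSection()
    align: AlignSection = AlignSection()
    variants: VariantSection = VariantSection()
    synteny: SyntenySection = SyntenySection()
    tm: TmSection = TmSection()
    screen: ScreenSection = ScreenSection()
    marker: MarkerSection = MarkerSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )
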
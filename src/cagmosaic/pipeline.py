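"""Pipeline composition: genotype -> eligibility -> expansion ratio ->
cohort models, with a single configuration object."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .cohort_models import adjusted_group_comparison, assign_category, fit_all_categories
from .errors import CagMosaicError, SchemaError
from .io import profiles_frame, read_fastq, write_json, write_tsv
from .mosaicism import (
    DEFAULT_GUARD,
    DEFAULT_WINDOW,
    BaselineModel,
    allele_eligibility,
    compute_expansion_ratio,
    is_genuine_expansion,
)
from .repeat_genotyper import LocusConfig, SampleGenotype, decompose_reads, genotype_sample
from .synthetic_data import StutterParams, expected_measured_ratios

logger = logging.getLogger("cagmosaic")

METADATA_COLUMNS = ("sample_id", "age_at_sampling", "group")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serialisable)."""

    locus: LocusConfig = dc_field(default_factory=LocusConfig)
    window: int = DEFAULT_WINDOW
    guard: int = DEFAULT_GUARD
    baseline_source: str = "simulator"   # or path to a baseline JSON
    regression_mode: str = "table1"      # or "results_text"
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.guard < 0:
            raise ValueError("guard must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        locus = LocusConfig(**data.pop("locus", {}))
        cfg = cls(locus=locus, **data)
        if cfg.baseline_source != "simulator" and not Path(cfg.baseline_source).exists():
            raise FileNotFoundError(
                f"baseline_source path not resolvable: {cfg.baseline_source}")
        return cfg

    def to_dict(self) -> dict:
        return {
            "locus": self.locus.to_dict(),
            "window": self.window,
            "guard": self.guard,
            "baseline_source": self.baseline_source,
            "regression_mode": self.regression_mode,
            "error_rate": self.error_rate,
            "seed": self.seed,
        }

    def baseline_for(self, inherited_cag: int) -> BaselineModel:
        """Stutter-only baseline ratio for an inherited length.

        Either loaded from a measured single-molecule baseline JSON or
        computed from the calibrated stutter model's exact expectation.
        """
        if self.baseline_source != "simulator":
            baseline = BaselineModel.from_json(self.baseline_source)
            if baseline.inherited_cag != inherited_cag:
                raise CagMosaicError(
                    f"baseline JSON is for {baseline.inherited_cag} CAG, "
                    f"sample inherited {inherited_cag}")
            return baseline
        params = StutterParams.calibrated_default()
        ratios = expected_measured_ratios(
            {inherited_cag: 1.0}, inherited_cag, params,
            error_rate=self.error_rate, window=self.window)
        return BaselineModel(inherited_cag=inherited_cag,
                             baseline_ratio=float(sum(ratios.values())),
                             source="simulator")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    for col in METADATA_COLUMNS:
        if col not in metadata.columns:
            raise SchemaError(f"metadata table is missing required column {col!r}")
    bad = metadata.index[metadata["age_at_sampling"].isna()]
    if len(bad):
        raise SchemaError(f"missing age_at_sampling in row(s) {list(bad[:5])}")
    out = metadata.copy()
    if "tissue" not in out.columns:
        out["tissue"] = "blood"
    return out


def genotype_reads(
    reads: Iterable[tuple[str, str]],
    locus: LocusConfig | None = None,
) -> SampleGenotype:
    """Decompose reads and call the sample's inherited alleles."""
    locus = locus or LocusConfig()
    calls = decompose_reads(reads, locus)
    return genotype_sample(
        calls,
        min_reads=locus.min_reads,
        homozygosity_fraction=locus.homozygosity_fraction,
        stutter_window=locus.stutter_absorb_window,
        min_peak_fraction=locus.min_peak_fraction,
    )


def sample_profiles(
    sample_id: str,
    genotype: SampleGenotype,
    config: PipelineConfig,
    tissue: str = "blood",
) -> list[tuple]:
    """Expansion profiles plus eligibility and genuineness for one sample.

    Returns rows of (profile, eligible, reason, genuine_or_None); a profile
    is scored against the stutter baseline only when its allele is eligible.
    """
    eligibility = allele_eligibility(genotype, window=config.window, guard=config.guard)
    roles = [("long", genotype.allele_long)]
    if not genotype.is_homozygous:
        roles.append(("short", genotype.allele_short))
    rows = []
    for role, allele in roles:
        eligible, reason = eligibility[role]
        profile = compute_expansion_ratio(
            genotype.histogram_by_structure, allele, window=config.window,
            sample_id=sample_id, allele_role=role, tissue=tissue)
        genuine = None
        if eligible:
            baseline = config.baseline_for(allele.cag)
            genuine, _ = is_genuine_expansion(profile, baseline)
        rows.append((profile, eligible, reason, genuine))
    return rows


def run_pipeline(
    config: PipelineConfig,
    fastq_by_sample: Mapping[str, object],
    metadata: pd.DataFrame,
    out_dir=None,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Full composition: genotype -> eligibility -> ratio -> cohort models.

    ``fastq_by_sample`` maps sample_id to a FASTQ path (str/Path) or an
    in-memory iterable of (read_id, sequence).  Returns (profiles table,
    regression report, cohort table) and, if ``out_dir`` is given, writes
    provenance-headed TSV/JSON files there, removing partial outputs on
    failure.
    """
    metadata = validate_metadata(metadata)
    meta_by_id = metadata.set_index("sample_id")
    written: list[Path] = []
    try:
        all_rows = []
        cohort_rows = []
        for sample_id, source in fastq_by_sample.items():
            if sample_id not in meta_by_id.index:
                raise SchemaError(f"sample {sample_id!r} absent from metadata")
            reads = read_fastq(source) if isinstance(source, (str, Path)) else source
            genotype = genotype_reads(reads, config.locus)
            tissue = str(meta_by_id.loc[sample_id, "tissue"])
            rows = sample_profiles(sample_id, genotype, config, tissue=tissue)
            all_rows.extend(rows)
            for profile, eligible, _reason, _genuine in rows:
                if not eligible:
                    continue
                cohort_rows.append({
                    "sample_id": sample_id,
                    "inherited_cag": profile.inherited_cag,
                    "age_at_sampling": float(meta_by_id.loc[sample_id, "age_at_sampling"]),
                    "group": str(meta_by_id.loc[sample_id, "group"]),
                    "category": assign_category(profile.inherited_cag),
                    "ratio": profile.ratio,
                })
            logger.info("sample %s: genotype %d/%d, %d pass reads", sample_id,
                        genotype.allele_short.cag, genotype.allele_long.cag,
                        genotype.total_pass_reads)
        profiles = profiles_frame(all_rows)
        cohort = pd.DataFrame(cohort_rows)
        report: dict = {"categories": {}}
        if len(cohort):
            fits = fit_all_categories(cohort, mode=config.regression_mode)
            report["categories"] = {k: v.to_dict() for k, v in fits.items()}
            if cohort["group"].nunique() == 2:
                try:
                    report["group_comparison"] = adjusted_group_comparison(cohort)
                except CagMosaicError as exc:
                    logger.warning("group comparison skipped: %s", exc)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            cfg = config.to_dict()
            p = out_dir / "profiles.tsv"
            write_tsv(profiles, p, cfg, config.seed); written.append(p)
            p = out_dir / "cohort.tsv"
            write_tsv(cohort, p, cfg, config.seed); written.append(p)
            p = out_dir / "regression_report.json"
            write_json(report, p, cfg, config.seed); written.append(p)
        return profiles, report, cohort
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
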
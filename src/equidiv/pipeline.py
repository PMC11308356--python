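"""Single-config orchestration of the full analysis.

``run_all`` executes, per population: QC (two profiles), heterozygosity,
ROH detection, F_ROH, per-class descriptive table, ROH-island incidence
and calling, the LD-based Ne trajectory, and — when a pedigree is supplied
— generation equivalents, pedigree inbreeding, coancestry-rate Ne and the
F_ROH ~ F_PED correlation.  Island overlap between the first two
populations and the genotype-free coverage validation round out the
bundle.  Every stage writes a TSV under the output directory and a
machine-readable manifest (inputs, parameters, version, file hashes) makes
the run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import expected_het, observed_het
from .io_plink import read_plink
from .ne_ld import NeConfig, estimate_ne
from .pedigree import Pedigree, ne_coancestry, pedigree_summary
from .qc import QCConfig, apply_qc, pca
from .roh import ROHParams, detect_roh
from .roh_stats import (
    GenomeLengths,
    call_islands,
    coverage_validation,
    descriptive_table,
    froh,
    froh_fped_correlation,
    froh_summary,
    island_incidence,
    islands_to_frame,
    islands_to_intervals,
    overlap_islands,
)
from .io_plink import export_bed

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


@dataclass
class RunConfig:
    """Everything needed to re-execute one analysis run."""

    populations: dict[str, str]  # name -> PLINK prefix
    out_dir: str
    metadata: dict[str, str] = field(default_factory=dict)  # name -> TSV
    qc_roh: QCConfig = field(default_factory=lambda: QCConfig.profile("roh"))
    qc_diversity: QCConfig = field(
        default_factory=lambda: QCConfig.profile("diversity")
    )
    roh_params: ROHParams = field(default_factory=ROHParams)
    ne_config: NeConfig = field(default_factory=NeConfig)
    ne_birth_years: dict[str, tuple[int, int]] = field(default_factory=dict)
    island_threshold: float = 0.70
    l_auto_override_bp: int | None = None
    pedigree_path: str | None = None
    pedigree_population: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "qc_roh" in kwargs:
            kwargs["qc_roh"] = QCConfig(**kwargs["qc_roh"])
        if "qc_diversity" in kwargs:
            kwargs["qc_diversity"] = QCConfig(**kwargs["qc_diversity"])
        if "roh_params" in kwargs:
            kwargs["roh_params"] = ROHParams(**kwargs["roh_params"])
        if "ne_config" in kwargs:
            kwargs["ne_config"] = NeConfig(**kwargs["ne_config"])
        if "ne_birth_years" in kwargs:
            kwargs["ne_birth_years"] = {
                k: tuple(v) for k, v in kwargs["ne_birth_years"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "populations": dict(self.populations),
            "out_dir": self.out_dir,
            "metadata": dict(self.metadata),
            "qc_roh": asdict(self.qc_roh),
            "qc_diversity": asdict(self.qc_diversity),
            "roh_params": asdict(self.roh_params),
            "ne_config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.ne_config).items()
            },
            "ne_birth_years": {k: list(v) for k, v in self.ne_birth_years.items()},
            "island_threshold": self.island_threshold,
            "l_auto_override_bp": self.l_auto_override_bp,
            "pedigree_path": self.pedigree_path,
            "pedigree_population": self.pedigree_population,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    def validate(self) -> None:
        for name, prefix in self.populations.items():
            p = Path(prefix)
            if not (
                p.parent.joinpath(p.name + ".bed").exists()
                or p.parent.joinpath(p.name + ".ped").exists()
            ):
                raise FileNotFoundError(
                    f"population {name!r}: no PLINK files at prefix {prefix}"
                )
        if self.pedigree_path is not None and not Path(self.pedigree_path).exists():
            raise FileNotFoundError(f"pedigree file {self.pedigree_path} not found")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    already written are retained alongside a FAILED marker file.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    froh_tables: dict[str, pd.DataFrame] = {}
    island_sets: dict[str, list] = {}
    try:
        for name, prefix in cfg.populations.items():
            stage = f"{name}:load"
            g_raw = read_plink(prefix, metadata=cfg.metadata.get(name))

            stage = f"{name}:qc"
            g_roh, rep_roh = apply_qc(g_raw, cfg.qc_roh)
            g_div, rep_div = apply_qc(g_raw, cfg.qc_diversity)
            save(rep_roh.to_frame(), f"{name}.qc_roh.tsv")
            save(rep_div.to_frame(), f"{name}.qc_diversity.tsv")
            save(pca(g_div, k=2), f"{name}.pca.tsv")

            stage = f"{name}:het"
            het = observed_het(g_div)
            save(het, f"{name}.het.tsv")
            cohort = expected_het(g_div)
            save(
                pd.DataFrame([vars(cohort)]),
                f"{name}.het_cohort.tsv",
            )

            stage = f"{name}:roh"
            runs = detect_roh(g_roh, cfg.roh_params)
            save(runs, f"{name}.roh.tsv")
            lengths = GenomeLengths.from_marker_map(
                g_roh.markers, cfg.l_auto_override_bp
            )
            ftab = froh(runs, g_roh.sample_ids, lengths)
            froh_tables[name] = ftab
            save(ftab, f"{name}.froh.tsv")
            save(froh_summary(ftab), f"{name}.froh_summary.tsv")
            save(descriptive_table(runs, g_roh.n_samples), f"{name}.roh_classes.tsv")

            stage = f"{name}:islands"
            inc = island_incidence(runs, g_roh)
            save(inc, f"{name}.incidence.tsv")
            islands = call_islands(inc, cfg.island_threshold)
            island_sets[name] = islands
            save(islands_to_frame(islands), f"{name}.islands.tsv")
            bed_path = out / f"{name}.islands.bed"
            export_bed(islands_to_intervals(islands), bed_path)
            written.append(bed_path)

            stage = f"{name}:coverage"
            covered = coverage_validation(g_roh.markers, cfg.roh_params, lengths)
            (out / f"{name}.coverage_check.txt").write_text(
                f"detectable_fraction\t{covered:.6f}\n"
            )
            written.append(out / f"{name}.coverage_check.txt")

            stage = f"{name}:ne"
            ne_cfg = cfg.ne_config
            if name in cfg.ne_birth_years:
                ne_cfg = NeConfig(
                    **{
                        **asdict(ne_cfg),
                        "birth_year_range": cfg.ne_birth_years[name],
                    }
                )
            save(estimate_ne(g_div, ne_cfg), f"{name}.ne.tsv")

        if len(cfg.populations) >= 2:
            stage = "islands_shared"
            names = list(cfg.populations)
            shared = overlap_islands(island_sets[names[0]], island_sets[names[1]])
            save(shared, "islands_shared.tsv")

        if cfg.pedigree_path is not None:
            stage = "pedigree"
            ped = Pedigree.read(cfg.pedigree_path)
            pop = cfg.pedigree_population or next(iter(cfg.populations))
            ftab = froh_tables[pop]
            in_ped = [s for s in ftab["sample_id"] if s in ped.records]
            summary = pedigree_summary(ped, in_ped if in_ped else None)
            save(summary, "pedigree.tsv")
            if len(in_ped) >= 2:
                ne_ped, rate = ne_coancestry(ped, in_ped)
                (out / "pedigree_ne.txt").write_text(
                    f"ne_coancestry\t{ne_ped:.4f}\nmean_delta_c\t{rate:.8f}\n"
                )
                written.append(out / "pedigree_ne.txt")
            if len(in_ped) >= 3:
                r, p = froh_fped_correlation(ftab, summary)
                (out / "froh_fped_correlation.txt").write_text(
                    f"r\t{r:.6f}\np\t{p:.3e}\n"
                )
                written.append(out / "froh_fped_correlation.txt")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    cfg.to_yaml(out / "config.yaml")
    written.append(out / "config.yaml")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": dict(cfg.populations),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
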
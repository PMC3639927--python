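"""End-to-end orchestration: simulate -> call -> popstats -> ld -> correlate.

A run is fully determined by its configuration (which embeds the seed); the
output bundle is byte-identical across runs with the same config.  Every run
writes a machine-readable manifest recording the resolved configuration and
a SHA-256 digest of each output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cnv_detection import (
    DetectionParams,
    call_rule_based,
    call_window,
    consensus,
    regions_stats_table,
)
from .core import ConfigError, PipelineError, overlap_bp
from .io_formats import (
    write_genotype_table,
    write_population_summary,
    write_probe_table,
    write_regions_bed,
)
from .ld_analysis import ld_table
from .popgen_stats import population_summaries, spearman_correlation
from .synthetic_data import (
    ACGHSimParams,
    DEFAULT_DELETION,
    PopulationModel,
    simulate_pool_acgh,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one reproducible run."""

    seed: int
    reference: str
    populations: list[PopulationModel]
    acgh: ACGHSimParams
    detection: DetectionParams = field(default_factory=DetectionParams)

    def __post_init__(self):
        names = [m.name for m in self.populations]
        if self.reference not in names:
            raise ConfigError(f"reference population {self.reference!r} not defined")
        if len(set(names)) != len(names):
            raise ConfigError("duplicate population names")

    @property
    def test_models(self) -> list[PopulationModel]:
        return [m for m in self.populations if m.name != self.reference]

    @property
    def reference_model(self) -> PopulationModel:
        return next(m for m in self.populations if m.name == self.reference)

    @classmethod
    def from_dict(cls, d: dict, seed_override: int | None = None) -> "RunConfig":
        try:
            seed = int(seed_override if seed_override is not None else d["seed"])
            populations = [
                PopulationModel(
                    name=p["name"],
                    n_individuals=int(p["n"]),
                    haplotype_freqs=tuple(float(x) for x in p["haplotype_freqs"]),
                )
                for p in d["populations"]
            ]
            acgh_d = dict(d.get("acgh", {}))
            interval = acgh_d.pop("deletion_interval", None)
            if interval is not None:
                interval = (str(interval[0]), int(interval[1]), int(interval[2]))
            else:
                interval = DEFAULT_DELETION
            acgh = ACGHSimParams(seed=seed, deletion_interval=interval, **acgh_d)
            detection = DetectionParams(**d.get("detection", {}))
            return cls(
                seed=seed,
                reference=d["reference"],
                populations=populations,
                acgh=acgh,
                detection=detection,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path, seed_override: int | None = None) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".toml", ".tml"):
            import tomllib

            d = tomllib.loads(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d, seed_override=seed_override)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "reference": self.reference,
            "populations": [
                {
                    "name": m.name,
                    "n": m.n_individuals,
                    "haplotype_freqs": list(m.haplotype_freqs),
                }
                for m in self.populations
            ],
            "acgh": {
                "probe_spacing": self.acgh.probe_spacing,
                "noise_sd": self.acgh.noise_sd,
                "attenuation": self.acgh.attenuation,
                "deletion_interval": list(self.acgh.deletion_interval),
                "flank_probes": self.acgh.flank_probes,
                "probe_length": self.acgh.probe_length,
                "min_probes": self.acgh.min_probes,
            },
            "detection": dataclasses.asdict(self.detection),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def pooled_intensity(probe_table, truth_region) -> float:
    """Mean combined dye-swap signal over probes inside a truth interval."""
    from .cnv_detection import combined_signal

    df = probe_table.probes
    inside = df[
        (df["chrom"] == truth_region.chrom)
        & (df["start"] < truth_region.end)
        & (df["end"] > truth_region.start)
    ]
    if len(inside) == 0:
        raise ValueError("no probes overlap the truth interval")
    return float(
        inside.apply(lambda r: combined_signal(r["log2_direct"], r["log2_swap"]), axis=1).mean()
    )


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline, writing the output bundle into ``out_dir``.

    Returns the manifest dictionary.  Any stage failure removes the partial
    outputs and raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _track(path: Path) -> Path:
        written.append(path)
        return path

    try:
        stage = "simulate"
        sim = simulate_pool_acgh(config.test_models, config.reference_model, config.acgh)
        write_genotype_table(sim.genotypes, _track(out / "genotypes.tsv"))
        for comparison_id in sorted(sim.probe_tables):
            write_probe_table(
                sim.probe_tables[comparison_id], _track(out / f"probes_{comparison_id}.tsv")
            )
        write_regions_bed(sim.truth_regions, _track(out / "truth.bed"))
        logger.info(
            "simulate: %d populations, %d comparisons, %d truth regions",
            len(config.populations),
            len(sim.probe_tables),
            len(sim.truth_regions),
        )

        stage = "call-cnv"
        all_consensus = []
        for comparison_id in sorted(sim.probe_tables):
            table = sim.probe_tables[comparison_id]
            rule = call_rule_based(table, config.detection)
            window = call_window(table, config.detection)
            cons = consensus(rule, window, config.detection.concordance_overlap)
            all_consensus.extend(cons)
            logger.info(
                "call-cnv %s: rule=%d window=%d consensus=%d",
                comparison_id,
                len(rule),
                len(window),
                len(cons),
            )
        write_regions_bed(all_consensus, _track(out / "consensus.bed"))
        regions_stats_table(all_consensus).to_csv(
            _track(out / "consensus_stats.tsv"), sep="\t", index=False
        )

        stage = "popstats"
        truth_by_comparison = {t.comparison_id: t for t in sim.truth_regions}
        pooled = {config.reference: 0.0}
        for model in config.test_models:
            comparison_id = f"{model.name}_vs_{config.reference}"
            truth = truth_by_comparison.get(comparison_id)
            if truth is not None:
                pooled[model.name] = pooled_intensity(sim.probe_tables[comparison_id], truth)
            else:
                # no copy-number difference simulated; intensity is flat
                from .cnv_detection import combined_signal

                df = sim.probe_tables[comparison_id].probes
                pooled[model.name] = float(
                    df.apply(
                        lambda r: combined_signal(r["log2_direct"], r["log2_swap"]), axis=1
                    ).mean()
                )
        summaries = population_summaries(sim.genotypes, pooled_log2=pooled)
        write_population_summary(summaries, _track(out / "population_summary.tsv"))

        stage = "ld"
        ld = ld_table(sim.genotypes)
        ld.to_csv(_track(out / "ld.tsv"), sep="\t", index=False, float_format="%.6f")

        stage = "correlate"
        xs, ys = [], []
        for s in summaries:
            if s.pooled_log2 is not None and s.cnv_allele_freqs is not None:
                xs.append(s.pooled_log2)
                ys.append(s.cnv_allele_freqs[1])  # deleted-allele %
        if len(xs) >= 3:
            rho, p = spearman_correlation(xs, ys)
            corr = {"rho": rho, "abs_rho": abs(rho), "p_value": p, "n": len(xs)}
        else:
            corr = {"rho": None, "abs_rho": None, "p_value": None, "n": len(xs)}
        (_track(out / "correlation.json")).write_text(
            json.dumps(corr, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

        stage = "manifest"
        manifest = {
            "package": "lce-cnvpop",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": {p.name: _sha256(p) for p in sorted(written, key=lambda p: p.name)},
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True).encode()
        ).hexdigest()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


REPORT_COLUMNS = [
    "population",
    "n",
    "cnv_pp_pct",
    "cnv_het_pct",
    "cnv_mm_pct",
    "cnv_plus_pct",
    "cnv_minus_pct",
    "snp_aa_pct",
    "snp_ag_pct",
    "snp_gg_pct",
]


def report_table(summaries) -> str:
    """Fixed-width plain-text table mirroring the published layout."""
    from .io_formats import MISSING

    def _cell(value, nd=2):
        if value is None:
            return MISSING
        if isinstance(value, float):
            return f"{value:.{nd}f}"
        return str(value)

    rows = []
    for s in summaries:
        cnv = s.cnv_genotype_freqs or (None, None, None)
        snp = s.snp_genotype_freqs or (None, None, None)
        allele = s.cnv_allele_freqs or (None, None)
        rows.append(
            [
                s.population,
                str(s.n),
                _cell(cnv[0]),
                _cell(cnv[1]),
                _cell(cnv[2]),
                _cell(allele[0]),
                _cell(allele[1]),
                _cell(snp[0]),
                _cell(snp[1]),
                _cell(snp[2]),
            ]
        )
    widths = [
        max(len(REPORT_COLUMNS[i]), *(len(r[i]) for r in rows)) if rows else len(REPORT_COLUMNS[i])
        for i in range(len(REPORT_COLUMNS))
    ]
    lines = ["  ".join(c.ljust(w) for c, w in zip(REPORT_COLUMNS, widths)).rstrip()]
    for r in rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"
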
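"""Pipeline orchestration: configuration, staged execution, run manifest.

A :class:`RunConfig` carries every tunable threshold with the study
defaults (arm lengths 6..15, 2.0-fold single-gene / 1.7-fold operon
rules at p <= 0.05, -100..+50 promoter windows, last 3 shifts).  All
randomness flows from one root seed through named per-stage substreams,
so reruns with the same configuration are byte-identical; a manifest
records parameters, seeds and SHA-256 digests of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .genome_io import write_promoter_fasta, write_promoter_tsv
from .microarray import call_differential, calls_to_frame, group_operons, summarize_genes
from .motif_scan import scan_promoter_set
from .physiology import (
    respiration_rate_ratio,
    shift_percent_increase,
    uptake_percent_difference,
    uptake_rate,
)
from .synthetic_data import (
    simulate_atp_shift_series,
    simulate_expression_experiment,
    simulate_growth_oxygen,
    simulate_promoter_set,
    simulate_uptake_series,
    write_expression_tsv,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("lumenstarve")

_STAGES = ("promoters", "motifs", "expression", "atp", "uptake", "oxygen")


@dataclass
class RunConfig:
    """All pipeline thresholds, seeds and stage selection."""

    stages: tuple[str, ...] = _STAGES
    seed: int = 0
    out_dir: str = "lumenstarve_run"
    # motif scan
    kmin: int = 6
    kmax: int = 15
    # promoter extraction
    upstream: int = 100
    downstream: int = 50
    # differential expression
    fc_single: float = 2.0
    fc_operon: float = 1.7
    alpha: float = 0.05
    gap_threshold: int = 25
    # physiology
    n_last_shifts: int = 3
    # synthetic-stage sizes
    n_promoters: int = 20
    n_genes: int = 200
    n_reps: int = 3

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fc_single <= 1 or self.fc_operon <= 1:
            raise ValueError("fold thresholds must exceed 1")
        if not (1 <= self.kmin <= self.kmax):
            raise ValueError("need 1 <= kmin <= kmax")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream/downstream must be non-negative")
        if self.n_last_shifts < 1:
            raise ValueError("n_last_shifts must be >= 1")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML/key-value file; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage substream seed below 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages on fully simulated inputs.

    Returns (and writes) the manifest: version, parameters, per-stage
    seeds and output paths with SHA-256 digests.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    seeds: dict[str, int] = {}
    try:
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        outputs["config"] = "config.yaml"

        promoters = None
        if "promoters" in config.stages:
            seeds["promoters"] = stage_seed(config.seed, "promoters")
            logger.info("simulating %d promoters", config.n_promoters)
            promoters, truth = simulate_promoter_set(
                config.n_promoters,
                plant_spec={"kind": "ir", "k": 6, "spacer": 2},
                seed=seeds["promoters"],
                kmin=config.kmin,
                kmax=config.kmax,
            )
            write_promoter_fasta(promoters, out / "promoters.fasta")
            write_promoter_tsv(promoters, out / "promoters.tsv")
            truth.to_json(out / "promoters_truth.json")
            outputs["promoters_fasta"] = "promoters.fasta"
            outputs["promoters_tsv"] = "promoters.tsv"
            outputs["promoters_truth"] = "promoters_truth.json"

        if "motifs" in config.stages:
            if promoters is None:
                raise ValueError("motif stage requires the promoter stage")
            report = scan_promoter_set(promoters, kmin=config.kmin, kmax=config.kmax)
            rows = ["seq_id\tclass\tk\toligo\tpositions\tdetail"]
            for scan in report.sequences:
                for h in scan.inverted_repeats:
                    rows.append(
                        f"{scan.seq_id}\tinverted_repeat\t{h.k}\t{h.oligo}\t"
                        f"{h.left_start},{h.right_start}\tspacer={h.spacer}"
                    )
                for pr in scan.overlapping_pairs:
                    rows.append(
                        f"{scan.seq_id}\toverlapping_pair\t{pr.first.k}\t"
                        f"{pr.first.oligo}|{pr.second.oligo}\t"
                        f"{pr.first.left_start},{pr.second.left_start}\toverlap={pr.overlap_len}"
                    )
                for td in scan.tandem_inverted:
                    rows.append(
                        f"{scan.seq_id}\ttandem_inverted\t{td.k}\t{td.oligo}\t"
                        f"{','.join(map(str, td.starts))}\t"
                        f"orient={'/'.join(td.orientations)}"
                    )
            (out / "motifs.tsv").write_text("\n".join(rows) + "\n")
            (out / "motif_counts.json").write_text(json.dumps(report.counts, indent=2) + "\n")
            outputs["motifs"] = "motifs.tsv"
            outputs["motif_counts"] = "motif_counts.json"

        if "expression" in config.stages:
            seeds["expression"] = stage_seed(config.seed, "expression")
            de_spec = [
                {"genes": ["g00000"], "fold": 2.5, "direction": "up_in_light"},
                {"genes": ["g00010", "g00011", "g00012"], "fold": 1.8, "direction": "up_in_dark"},
            ]
            experiment, annotations, truth = simulate_expression_experiment(
                config.n_genes, n_reps=config.n_reps, de_spec=de_spec, seed=seeds["expression"]
            )
            write_expression_tsv(experiment, out / "intensities.tsv", out / "samples.tsv")
            truth.to_json(out / "expression_truth.json")
            summaries = summarize_genes(experiment)
            operons = group_operons(annotations, gap_threshold=config.gap_threshold)
            calls = call_differential(
                summaries, operons,
                fc_single=config.fc_single, fc_operon=config.fc_operon, alpha=config.alpha,
            )
            summaries.to_csv(out / "gene_summaries.tsv", sep="\t")
            calls_to_frame(calls).to_csv(out / "de_calls.tsv", sep="\t", index=False)
            outputs.update(
                {
                    "intensities": "intensities.tsv",
                    "samples": "samples.tsv",
                    "expression_truth": "expression_truth.json",
                    "gene_summaries": "gene_summaries.tsv",
                    "de_calls": "de_calls.tsv",
                }
            )
            logger.info("DE calling produced %d calls", len(calls))

        physio: dict[str, object] = {}
        if "atp" in config.stages:
            seeds["atp"] = stage_seed(config.seed, "atp")
            series, truth = simulate_atp_shift_series(
                n_shifts=4, true_boost_percent=36.0, seed=seeds["atp"]
            )
            result = shift_percent_increase(series, n_last=config.n_last_shifts)
            physio["atp_boost_percent_mean"] = result.mean
            physio["atp_boost_percent_sd"] = result.sd
            physio["atp_true_boost_percent"] = truth.physiology["true_boost_percent"]
        if "uptake" in config.stages:
            seeds["uptake"] = stage_seed(config.seed, "uptake")
            light, dark, truth = simulate_uptake_series(seed=seeds["uptake"])
            lr, dr = uptake_rate(light), uptake_rate(dark)
            physio["uptake_rate_light_dpm_min"] = lr.rate
            physio["uptake_rate_dark_dpm_min"] = dr.rate
            physio["uptake_percent_difference"] = uptake_percent_difference(lr.rate, dr.rate)
        if "oxygen" in config.stages:
            seeds["oxygen"] = stage_seed(config.seed, "oxygen")
            light, dark, truth = simulate_growth_oxygen(seed=seeds["oxygen"])
            ratio = respiration_rate_ratio(light, dark)
            ratio.to_csv(out / "respiration_ratios.tsv", sep="\t", index=False)
            outputs["respiration_ratios"] = "respiration_ratios.tsv"
            stationary = ratio[ratio["t_start_h"] >= truth.physiology["stationary_start_h"]]
            if len(stationary):
                physio["stationary_light_dark_ratio"] = float(
                    stationary["light_dark_ratio"].mean()
                )
        if physio:
            (out / "physiology_estimates.json").write_text(json.dumps(physio, indent=2) + "\n")
            outputs["physiology_estimates"] = "physiology_estimates.json"

        manifest = {
            "version": __version__,
            "root_seed": config.seed,
            "stage_seeds": seeds,
            "parameters": config.to_dict(),
            "outputs": {
                name: {"path": rel, "sha256": _sha256(out / rel)}
                for name, rel in outputs.items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        logger.info("run complete: %d outputs", len(outputs))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
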
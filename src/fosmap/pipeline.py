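"""End-to-end orchestration: counts (real or synthetic) -> activation
statistics -> response clustering -> per-group functional networks,
with a machine-readable summary of the headline numbers.

The same config and seed always produce a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import regions as _regions
from .activation import ActivationAnalysis, coactivated_regions
from .cluster import ResponseClustering, to_newick
from .network import CorrelationNetwork, export_edgelist, export_graphml, write_correlation_csv
from .regions import Contrast, RegionOntology, aggregate_to_level, load_counts, load_ontology
from .simulate import SynthConfig, generate_counts

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_config", "load_config"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: str = "fosmap_out"
    seed: int = 0
    synth: SynthConfig | None = None
    counts_path: str | None = None
    ontology_path: str | None = None
    level: str | None = None
    contrasts: tuple[Contrast, ...] = _regions.CANONICAL_CONTRASTS
    q: float = 0.05
    effect_fraction: float = 0.40
    cluster_cut: float = 0.5
    module_cut: float = 0.7
    r_min: float = 0.82
    alpha: float = 0.05
    hub_quantile: float = 0.80
    features: str = "animals"
    method: str = "zmean"
    control_mean: str = "raw"
    missing_policy: str = "error"

    def validate(self) -> list[str]:
        errors = []
        for name, lo, hi in [
            ("q", 0, 1),
            ("effect_fraction", 0, 1),
            ("cluster_cut", 0, 1),
            ("module_cut", 0, 1),
            ("alpha", 0, 1),
            ("hub_quantile", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                errors.append(f"{name}={v} out of range ({lo}, {hi}]")
        if not -1 <= self.r_min <= 1:
            errors.append(f"r_min={self.r_min} out of range [-1, 1]")
        if self.synth is None and self.counts_path is None:
            errors.append("either 'synth' or 'counts' input must be given")
        for attr in ("counts_path", "ontology_path"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                errors.append(f"{attr.removesuffix('_path')} file not found: {path}")
        if self.level not in (None, "coarse53", "division"):
            errors.append(f"level={self.level!r} must be 'coarse53' or 'division'")
        if self.features not in ("animals", "mean"):
            errors.append(f"features={self.features!r} must be 'animals' or 'mean'")
        if self.method not in ("zmean", "t", "wilcoxon", "auto"):
            errors.append(f"method={self.method!r} unknown")
        if self.control_mean not in ("raw", "geometric"):
            errors.append(f"control_mean={self.control_mean!r} unknown")
        return errors


def load_config(path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    kwargs = dict(raw)
    if "synth" in kwargs and kwargs["synth"] is not None:
        synth = dict(kwargs["synth"])
        synth.setdefault("seed", kwargs.get("seed", 0))
        kwargs["synth"] = SynthConfig.from_dict(synth)
    if "counts" in kwargs:
        kwargs["counts_path"] = kwargs.pop("counts")
    if "ontology" in kwargs:
        kwargs["ontology_path"] = kwargs.pop("ontology")
    if "contrasts" in kwargs:
        kwargs["contrasts"] = tuple(Contrast(t, c) for t, c in kwargs["contrasts"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def validate_config(path) -> list[str]:
    """Schema-check a config file; returns a list of error messages."""
    try:
        cfg = load_config(path)
    except Exception as exc:
        return [str(exc)]
    return cfg.validate()


def _round(x: float, digits: int = 10) -> float:
    return float(f"{x:.{digits}g}") if np.isfinite(x) else None


def _ln_density_table(counts: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = counts[counts["group"] == group]
    wide = _regions.density_table(sub)
    with np.errstate(divide="ignore"):
        return np.log(wide).where(wide > 0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; writes per-stage outputs plus
    ``summary.json`` under ``config.output_dir`` and returns the summary."""
    errors = config.validate()
    if errors:
        raise PipelineError("config", ValueError("; ".join(errors)))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _track(path: Path) -> Path:
        written.append(path)
        return path

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {
            "seed": config.seed,
            "q": config.q,
            "effect_fraction": config.effect_fraction,
            "cluster_cut": config.cluster_cut,
            "module_cut": config.module_cut,
            "r_min": config.r_min,
            "alpha": config.alpha,
            "hub_quantile": config.hub_quantile,
            "method": config.method,
            "level": config.level,
        },
        "contrasts": {},
        "networks": {},
    }

    stage = "regions_io"
    try:
        ontology: RegionOntology | None = None
        if config.ontology_path is not None:
            ontology = load_ontology(config.ontology_path)
        truth = None
        if config.synth is not None:
            synth = dataclasses.replace(config.synth, seed=config.seed)
            counts, truth = generate_counts(synth)
            _regions.write_counts(counts, _track(outdir / "counts.csv"))
            truth_json = {
                "activated": {g: sorted(s) for g, s in truth.activated.items()},
                "modules": dict(sorted(truth.modules.items())),
                "hub": truth.hub,
            }
            _track(outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
        else:
            counts = load_counts(config.counts_path, ontology)
        if config.level is not None:
            if ontology is None:
                raise ValueError("aggregation to a coarser level requires an ontology")
            counts = aggregate_to_level(counts, ontology, config.level, missing=config.missing_policy)

        stage = "activation_stats"
        present = set(counts["group"])
        contrasts = [c for c in config.contrasts if {c.treatment, c.control} <= present]
        analyses: dict[str, ActivationAnalysis] = {}
        for contrast in contrasts:
            key = f"{contrast.treatment}_vs_{contrast.control}"
            an = ActivationAnalysis(
                treatment=contrast.treatment,
                control=contrast.control,
                q=config.q,
                effect_fraction=config.effect_fraction,
                method=config.method,
                control_mean=config.control_mean,
            ).fit(counts)
            analyses[key] = an
            an.stats_.to_csv(_track(outdir / f"{key}_region_stats.csv"))
            an.logrel_.to_csv(_track(outdir / f"{key}_log_relative.csv"))

            stage = "clustering"
            rc = ResponseClustering(cut_ratio=config.cluster_cut, features=config.features).fit(an.logrel_)
            cl = pd.DataFrame(
                {
                    "cluster": rc.labels_by_region_,
                    "z_value": an.stats_["z_value"].reindex(rc.labels_by_region_.index),
                }
            )
            cl.to_csv(_track(outdir / f"{key}_clusters.csv"))
            _track(outdir / f"{key}_dendrogram.nwk").write_text(to_newick(rc.dendrogram_))
            summ = rc.summarize(an.stats_["z_value"])
            summary["contrasts"][key] = {
                "n_regions_tested": int(an.stats_["p_raw"].notna().sum()),
                "n_significant": int(an.stats_["significant"].sum()),
                "n_selected": len(an.selected_),
                "selected": list(an.selected_),
                "cluster_k": rc.k_,
                "mean_silhouette": _round(rc.silhouette_),
                "cluster_mean_z": {
                    str(int(row["cluster"])): _round(row["mean_z"])
                    for _, row in summ["summary"].iterrows()
                },
            }
            stage = "activation_stats"

        if len(analyses) >= 2:
            (a, b) = list(analyses)[:2]
            common, per_division = coactivated_regions(
                analyses[a].stats_, analyses[b].stats_, ontology=ontology
            )
            summary["coactivated"] = {
                "contrasts": [a, b],
                "count": len(common),
                "regions": sorted(common),
                "per_division": dict(sorted(per_division.items())),
            }

        stage = "network"
        for group in sorted(present):
            lnd = _ln_density_table(counts, group)
            if lnd.shape[0] < 3:
                logger.warning("group %s has %d subject(s); skipping network", group, lnd.shape[0])
                continue
            net = CorrelationNetwork(
                r_min=config.r_min,
                alpha=config.alpha,
                module_cut=config.module_cut,
                hub_quantile=config.hub_quantile,
            ).fit(lnd)
            write_correlation_csv(net.correlation_, _track(outdir / f"correlation_{group}.csv"))
            export_edgelist(net.graph_, _track(outdir / f"network_{group}_edges.csv"))
            export_graphml(
                net.graph_, net.centralities_, net.modules_, net.hubs_,
                _track(outdir / f"network_{group}.graphml"),
            )
            net.centralities_.to_csv(_track(outdir / f"centrality_{group}.csv"))
            summary["networks"][group] = {
                "n_nodes": int(net.graph_.number_of_nodes()),
                "n_edges": int(net.graph_.number_of_edges()),
                "density": _round(net.density_),
                "n_modules": net.n_modules_,
                "hubs": sorted(net.hubs_),
            }

        if truth is not None:
            summary["ground_truth_file"] = "ground_truth.json"

        stage = "summary"
        text = json.dumps(summary, sort_keys=True, indent=2)
        _track(outdir / "summary.json").write_text(text)
    except PipelineError:
        raise
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return summary
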
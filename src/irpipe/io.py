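"""Readers, writers, pipeline configuration, and the end-to-end runner.

Formats
-------
* Expression: TSV (first column gene id, header row of sample ids) or an
  MTX triplet with row/column annotation files.
* Gene sets: GMT. Orientation is encoded as paired entries ``NAME_UP`` /
  ``NAME_DN``: members of the ``_DN`` entry get orientation -1 and the
  pair merges into one signature. Unpaired entries are all +1.
* Phenotypes: long-format CSV with fixed column names (``subject``,
  ``timepoint``, ``age``, ``sex``, ``cd4``, ``cd8``, ``time``,
  ``event``); only the columns a stage needs must be present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import signatures as sig
from . import survival as surv
from . import trajectories as traj
from .ihg import IHGThresholds, assign_ihg, is_extreme_degrader
from .signatures import GeneSignature
from .triad import ReadoutPanel, triad_burden

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_phenotypes",
    "PipelineConfig",
    "config_hash",
    "run_pipeline",
]


def read_expression(
    path,
    format: str = "tsv",
    genes_path=None,
    samples_path=None,
) -> pd.DataFrame:
    """Load a genes x samples expression matrix.

    For ``format="mtx"`` pass the triplet file plus ``genes_path`` and
    ``samples_path`` (one id per line, rows and columns respectively).
    Duplicate gene ids are an error.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    elif format == "mtx":
        if genes_path is None or samples_path is None:
            raise ValueError("mtx format requires genes_path and samples_path")
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(samples)} samples"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return sig.validate_expression(df)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write TSV that round-trips bit-identically through read_expression."""
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> list[GeneSignature]:
    """Parse GMT into oriented signatures (``_UP``/``_DN`` pairing dialect)."""
    up: dict[str, list[str]] = {}
    dn: dict[str, list[str]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            raise ValueError(f"{path}:{lineno}: gene set line with no genes")
        name, _desc, *genes = fields
        genes = [g for g in genes if g.strip()]
        if name.endswith("_UP"):
            base, bucket = name[:-3], up
        elif name.endswith("_DN"):
            base, bucket = name[:-3], dn
        else:
            base, bucket = name, up
        if base in bucket:
            raise ValueError(f"{path}:{lineno}: duplicate entry for {name!r}")
        bucket[base] = genes
        if base not in order:
            order.append(base)

    out = []
    for base in order:
        members = [(g, +1) for g in up.get(base, [])] + [(g, -1) for g in dn.get(base, [])]
        both = set(up.get(base, [])) & set(dn.get(base, []))
        if both:
            raise ValueError(f"genes in both _UP and _DN of {base!r}: {sorted(both)}")
        out.append(GeneSignature(base, members))
    return out


def write_gmt(signatures_: list[GeneSignature], path) -> None:
    lines = []
    for s in signatures_:
        ups = [g for g, o in s.members if o == +1]
        dns = [g for g, o in s.members if o == -1]
        if ups:
            suffix = "_UP" if dns else ""
            lines.append("\t".join([f"{s.name}{suffix}", s.role, *ups]))
        if dns:
            lines.append("\t".join([f"{s.name}_DN", s.role, *dns]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotypes(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Phenotype CSV; raises naming any missing required column."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing column(s): {missing}")
    return df


@dataclass
class PipelineConfig:
    """Everything the end-to-end runner needs, with stable defaults."""

    expression_path: str = ""
    gene_sets_path: str = ""
    phenotypes_path: str = ""
    out_dir: str = "irpipe_out"
    seed: int = 0
    # scoring
    aggregator: str = "mean"
    min_coverage: float = 0.5
    sas_signature: str = "SAS-1"
    mas_signature: str = "MAS-1"
    tcf7_gene: str = "TCF7"
    pos_readouts: tuple[str, ...] = ()
    neg_readouts: tuple[str, ...] = ()
    # ihg
    ihg_thresholds: IHGThresholds = field(default_factory=IHGThresholds)
    # survival
    ref_age: float = 40.0
    # screens
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError("fdr_level must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ihg_thresholds"] = dataclasses.asdict(self.ihg_thresholds)
        return d


def config_hash(config: PipelineConfig) -> str:
    """Stable hash over the semantically meaningful config fields."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Score -> stratify -> profile -> triad -> (ihg, trajectory) -> survival.

    Writes per-stage TSVs plus a JSON summary carrying the config hash
    and seed; returns the summary dict. Stages whose inputs are absent
    (e.g. no cd4/cd8 columns) are skipped and noted in the summary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config_hash(config), "seed": config.seed, "stages": {}}

    expr = read_expression(config.expression_path)
    gene_sets = {s.name: s for s in read_gmt(config.gene_sets_path)}
    z = sig.zscore_genes(expr)
    summary["stages"]["zscore"] = {"genes": int(z.shape[0]), "samples": int(z.shape[1]),
                                   "dropped_genes": int(expr.shape[0] - z.shape[0])}

    scores = pd.DataFrame(index=z.columns)
    strata = pd.DataFrame(index=z.columns)
    for name, s in gene_sets.items():
        scores[name] = sig.score_signature(z, s, config.min_coverage, config.aggregator)
        strata[name] = sig.stratify(scores[name])
    out = scores.copy()
    out.columns = [f"{c}_score" for c in out.columns]
    for name in gene_sets:
        out[f"{name}_stratum"] = strata[name]

    if config.sas_signature in scores and config.mas_signature in scores:
        out["profile"] = sig.make_profile(strata[config.sas_signature], strata[config.mas_signature])
    if config.tcf7_gene in expr.index:
        level, tcf7_strat = sig.tcf7_status(expr, config.tcf7_gene)
        out["tcf7_nge"] = level
        out["tcf7_stratum"] = tcf7_strat

    if config.pos_readouts and config.neg_readouts:
        panel = ReadoutPanel(
            pos={n: scores[n] for n in config.pos_readouts},
            neg={n: scores[n] for n in config.neg_readouts},
        )
        out["triad_burden"] = triad_burden(panel)
        summary["stages"]["triad"] = {"pos": list(config.pos_readouts), "neg": list(config.neg_readouts)}

    out.index.name = "sample"
    scores_path = out_dir / "scores.tsv"
    out.to_csv(scores_path, sep="\t")
    summary["stages"]["score"] = {"path": str(scores_path), "signatures": list(gene_sets)}

    pheno = None
    if config.phenotypes_path:
        pheno = read_phenotypes(config.phenotypes_path, required=("subject",))

    if pheno is not None and {"cd4", "cd8"} <= set(pheno.columns):
        grades = assign_ihg(pheno["cd4"], pheno["cd8"], config.ihg_thresholds)
        ihg_out = pd.DataFrame(
            {"subject": pheno["subject"], "ihg": grades, "extreme_degrader": is_extreme_degrader(grades)}
        )
        ihg_path = out_dir / "ihg.tsv"
        ihg_out.to_csv(ihg_path, sep="\t", index=False)
        summary["stages"]["ihg"] = {
            "path": str(ihg_path),
            "thresholds": dataclasses.asdict(config.ihg_thresholds),
        }

    if pheno is not None and "timepoint" in pheno.columns and "profile" in out.columns:
        long = pheno[["subject", "timepoint"]].copy()
        sample_col = pheno["sample"] if "sample" in pheno.columns else pheno["subject"]
        long["profile"] = out["profile"].reindex(sample_col.astype(str)).to_numpy()
        labels = traj.classify_trajectories(long)
        traj_path = out_dir / "trajectories.tsv"
        labels.to_frame().to_csv(traj_path, sep="\t")
        summary["stages"]["trajectory"] = {"path": str(traj_path),
                                           "counts": labels.value_counts().to_dict()}

    if pheno is not None and {"time", "event", "age"} <= set(pheno.columns) and "profile" in out.columns:
        df = pheno.drop_duplicates("subject").set_index("subject")
        prof = out["profile"].reindex(df.index.astype(str))
        df = df.assign(group=(prof == "L-H").astype(float).to_numpy())
        df = df[df["group"].notna() & prof.isin(["L-H", "H-L"]).to_numpy()]
        try:
            fit = surv.fit_ph(df, ["age", "group"])
            hr, hr_ci = surv.hazard_ratio(fit, "group")
            eq = surv.equivalence_age(fit, ref_age=config.ref_age)
            summary["stages"]["survival"] = {
                "coefficients": fit.coefficients.to_dict(),
                "hr_group": hr,
                "hr_group_ci": list(hr_ci),
                "equivalence_age": eq.equivalence_age,
                "survival_gap": eq.survival_gap,
                "converged": fit.converged,
                "n": fit.n,
                "events": fit.events,
            }
        except ValueError as exc:
            summary["stages"]["survival"] = {"skipped": str(exc)}

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    logger.info("pipeline complete; summary at %s", summary_path)
    return summary
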
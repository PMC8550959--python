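"""Readers, writers and configuration for all supported formats.

Canonical tabular dialect: tab-separated UTF-8 with a header row, first
column the subject id, missing cells written as ``NA``.  Genotypes load
from PLINK .ped/.map pairs, VCF (biallelic records only), or plain dosage
TSV.  Collections, relation graphs and partitions serialize to TSV and
JSON (sorted keys, no timestamps, so byte-identical across reruns).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .replicate import PipelineConfig, PipelineResult
from .synthetic import CohortConfig
from .types import (
    Bicluster,
    FeatureMatrix,
    NetworkPartition,
    PHENOTYPE_SCALES,
    Relation,
    RelationGraph,
    SetCollection,
)

MISSING = "NA"


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a subject column plus features")
    return df.set_index(df.columns[0])


def _numeric(df: pd.DataFrame, path) -> np.ndarray:
    vals = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw == MISSING or raw == "":
                vals[i, j] = np.nan
                continue
            try:
                vals[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {df.index[i]!r}, "
                    f"column {col!r}: {raw!r}"
                ) from None
    return vals


def infer_scale_schema(feature_ids) -> dict[str, str]:
    """Map subscale column names to scales by their alphabetic prefix."""
    schema = {}
    for f in feature_ids:
        prefix = "".join(c for c in f if c.isalpha())
        if prefix not in PHENOTYPE_SCALES:
            raise ValueError(
                f"column {f!r} (prefix {prefix!r}) is not in the known scales "
                f"{PHENOTYPE_SCALES}; pass an explicit schema"
            )
        schema[f] = prefix
    return schema


def load_phenotypes(path, schema: Optional[dict[str, str]] = None) -> FeatureMatrix:
    """Load a subjects x subscales TSV with scale metadata."""
    df = _read_table(path)
    if schema is None:
        schema = infer_scale_schema(df.columns)
    else:
        unknown = [c for c in df.columns if c not in schema]
        if unknown:
            raise ValueError(f"{path}: columns {unknown} missing from schema")
    vals = _numeric(df, path)
    return FeatureMatrix(vals, [str(i) for i in df.index],
                         [str(c) for c in df.columns], "phenotype", dict(schema))


def load_environment(path) -> FeatureMatrix:
    df = _read_table(path)
    return FeatureMatrix(_numeric(df, path), [str(i) for i in df.index],
                         [str(c) for c in df.columns], "environment")


def write_matrix(fm: FeatureMatrix, path) -> None:
    df = fm.to_frame()
    df.to_csv(path, sep="\t", na_rep=MISSING)


# ---------------------------------------------------------------------------
# genotypes: dosage TSV, PLINK .ped/.map, VCF
# ---------------------------------------------------------------------------

def load_genotypes(path) -> FeatureMatrix:
    """Load an additive dosage matrix from .tsv, .ped(/.map) or .vcf.

    Dosage counts the alternate allele for VCF, and the minor allele
    (frequency tie broken alphabetically) for .ped/.map, where no
    alternate is declared.  No strand flipping is attempted.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".tsv":
        df = _read_table(p)
        fm = FeatureMatrix(_numeric(df, p), [str(i) for i in df.index],
                           [str(c) for c in df.columns], "genotype")
    elif suffix == ".ped":
        fm = _load_ped(p, p.with_suffix(".map"))
    elif suffix in (".vcf", ".gz"):
        fm = _load_vcf(p)
    else:
        raise ValueError(f"unsupported genotype format: {p.name}")
    fm.validate_genotype()
    return fm


def _load_ped(ped_path: Path, map_path: Path) -> FeatureMatrix:
    snp_ids = []
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns")
            snp_ids.append(parts[1])
    subjects, rows = [], []
    with open(ped_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_ids):
                raise ValueError(
                    f"{ped_path}:{lineno}: {len(parts)} fields but .map "
                    f"declares {len(snp_ids)} SNPs (need {6 + 2 * len(snp_ids)})"
                )
            subjects.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(subjects), len(snp_ids), 2)
    vals = np.full((len(subjects), len(snp_ids)), np.nan)
    for j in range(len(snp_ids)):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        if observed.size == 0:
            continue
        uniq, counts = np.unique(observed, return_counts=True)
        order = sorted(zip(counts, uniq), key=lambda t: (t[0], t[1]))
        minor = order[0][1]
        missing = (col == "0").any(axis=1)
        vals[:, j] = np.where(missing, np.nan, (col == minor).sum(axis=1))
    return FeatureMatrix(vals, subjects, snp_ids, "genotype")


def _load_vcf(path: Path) -> FeatureMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = list(vcf.samples)
    snp_ids, cols = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan  # unknown genotype
        cols.append(gt)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} multiallelic records")
    vals = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return FeatureMatrix(vals, subjects, snp_ids, "genotype")


def write_ped(gen: FeatureMatrix, prefix) -> tuple[Path, Path]:
    """Write a dosage matrix as a PLINK .ped/.map pair.

    The counted allele is written as ``G`` and the other as ``A``; the
    pair round-trips with :func:`load_genotypes` whenever the counted
    allele is the minor one (dosage mean < 1).
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w", encoding="utf-8") as fh:
        for j, snp in enumerate(gen.feature_ids):
            fh.write(f"1\t{snp}\t0\t{j + 1}\n")
    allele_pairs = {0.0: ("A", "A"), 1.0: ("A", "G"), 2.0: ("G", "G")}
    with open(ped_path, "w", encoding="utf-8") as fh:
        for i, sid in enumerate(gen.subject_ids):
            row = [sid, sid, "0", "0", "0", "-9"]
            for v in gen.values[i]:
                a, b = ("0", "0") if np.isnan(v) else allele_pairs[float(v)]
                row.extend((a, b))
            fh.write("\t".join(row) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# collections / graphs / partitions
# ---------------------------------------------------------------------------

def write_collection(sc: SetCollection, path) -> None:
    path = Path(path)
    if path.suffix == ".tsv":
        sc.to_frame().to_csv(path, sep="\t", index=False)
        return
    doc = {
        "domain": sc.domain,
        "subject_universe": sc.subject_universe,
        "ranks_used": sc.ranks_used,
        "cophenetic": {str(k): v for k, v in sc.cophenetic.items()},
        "biclusters": [{
            "id": b.id, "domain": b.domain, "rank": b.rank,
            "factor_index": b.factor_index,
            "subject_ids": b.subject_ids, "feature_ids": b.feature_ids,
            "subject_weights": [float(w) for w in b.subject_weights],
            "feature_weights": [float(w) for w in b.feature_weights],
        } for b in sc.biclusters],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_collection(path) -> SetCollection:
    doc = json.loads(Path(path).read_text())
    bics = [Bicluster(
        id=b["id"], domain=b["domain"], subject_ids=b["subject_ids"],
        feature_ids=b["feature_ids"],
        subject_weights=np.asarray(b["subject_weights"]),
        feature_weights=np.asarray(b["feature_weights"]),
        rank=b["rank"], factor_index=b["factor_index"],
    ) for b in doc["biclusters"]]
    return SetCollection(
        biclusters=bics, subject_universe=doc["subject_universe"],
        domain=doc["domain"], ranks_used=doc["ranks_used"],
        cophenetic={int(k): v for k, v in doc["cophenetic"].items()},
    )


def write_graph(g: RelationGraph, path) -> None:
    path = Path(path)
    if path.suffix == ".tsv":
        g.to_frame().to_csv(path, sep="\t", index=False)
        return
    doc = {
        "alpha": g.alpha, "correction": g.correction, "n_perm": g.n_perm,
        "perm_alpha": g.perm_alpha, "seed": g.seed,
        "relations": g.to_frame().to_dict(orient="records"),
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_graph(path, source: SetCollection, target: SetCollection) -> RelationGraph:
    doc = json.loads(Path(path).read_text())
    rels = [Relation(
        source=r["source"], target=r["target"], overlap=int(r["overlap"]),
        n_source=int(r["n_source"]), n_target=int(r["n_target"]),
        cohort_size=source.cohort_size, p_hypergeom=r["p_hypergeom"],
        p_fisher=r["p_fisher"], p_empirical=r["p_empirical"],
        q_value=r["q_value"], significant=bool(r["significant"]),
    ) for r in doc["relations"]]
    return RelationGraph(
        relations=rels, source_collection=source, target_collection=target,
        alpha=doc["alpha"], correction=doc["correction"],
        n_perm=doc["n_perm"], perm_alpha=doc["perm_alpha"], seed=doc["seed"],
    )


def write_partition(p: NetworkPartition, path) -> None:
    doc = {
        "k": p.k,
        "set_networks": p.set_networks,
        "subject_networks": {s: g for s, g in p.subject_networks.items()},
        "ordered_by_wellbeing": p.ordered_by_wellbeing,
        "unassigned_fraction": p.unassigned_fraction,
        "network_sizes": {str(k): v for k, v in p.network_sizes().items()},
        "disjointness": p.disjointness,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_partition(path) -> NetworkPartition:
    doc = json.loads(Path(path).read_text())
    p = NetworkPartition(k=doc["k"], set_networks=doc["set_networks"])
    p.subject_networks = {s: g for s, g in doc["subject_networks"].items()}
    p.ordered_by_wellbeing = doc["ordered_by_wellbeing"]
    p.unassigned_fraction = doc["unassigned_fraction"]
    p.disjointness = doc.get("disjointness", {})
    return p


def save_pipeline_result(result: PipelineResult, outdir) -> Path:
    """Serialize a full pipeline result to a directory, deterministically."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_collection(result.temperament_sets, out / "temperament_sets.json")
    write_collection(result.character_sets, out / "character_sets.json")
    write_graph(result.relation_graph, out / "relations.tsv")
    write_graph(result.relation_graph, out / "relations.json")
    write_partition(result.partition, out / "partition.json")
    result.health.to_frame().to_csv(out / "health.tsv", sep="\t", index=False)
    comp = {
        name: {
            "outcome": c.outcome, "level": c.level,
            "group_means": {str(k): v for k, v in c.group_means.items()},
            "group_sds": {str(k): v for k, v in c.group_sds.items()},
            "group_ns": {str(k): v for k, v in c.group_ns.items()},
            "F": c.f_statistic, "df": [c.df_between, c.df_within],
            "p": c.p_value,
            "tukey": {f"{a}-{b}": v for (a, b), v in c.tukey_pvalues.items()},
            "zero_within_variance": c.zero_within_variance,
        } for name, c in result.comparisons.items()
    }
    (out / "comparisons.json").write_text(
        json.dumps(comp, indent=1, sort_keys=True) + "\n")
    if result.genotype_sets is not None:
        write_collection(result.genotype_sets, out / "genotype_sets.json")
    if result.environment_sets is not None:
        write_collection(result.environment_sets, out / "environment_sets.json")
    if result.snp_association is not None:
        assoc = {sid: sorted(gs) for sid, gs in result.snp_association.flags.items()}
        (out / "snp_network_associations.json").write_text(
            json.dumps(assoc, indent=1, sort_keys=True) + "\n")
    if result.env_report is not None:
        rep = {
            "direct": {e: sorted(gs) for e, gs in result.env_report.direct.items()},
            "indirect": {e: sorted(gs) for e, gs in result.env_report.indirect.items()},
            "mediators": {e: sorted(m) for e, m in result.env_report.mediators.items()},
            "counts": {"direct": result.env_report.n_direct,
                       "indirect": result.env_report.n_indirect,
                       "both": result.env_report.n_both},
        }
        (out / "environment_report.json").write_text(
            json.dumps(rep, indent=1, sort_keys=True) + "\n")
    if result.variance:
        var = {name: asdict(v) for name, v in result.variance.items()}
        (out / "variance.json").write_text(
            json.dumps(var, indent=1, sort_keys=True) + "\n")
    summary = dict(result.summary())
    summary["network_sizes"] = {str(k): v for k, v in summary["network_sizes"].items()}
    summary["stage_seeds"] = result.stage_seeds
    summary["config"] = asdict(result.config)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return out


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level configuration: cohort simulation + pipeline parameters."""

    cohort: CohortConfig
    pipeline: PipelineConfig
    inputs: dict = dataclasses.field(default_factory=dict)


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    if cls is CohortConfig and "maf_range" in section:
        section = {**section, "maf_range": tuple(section["maf_range"])}
    return cls(**section)


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - {"cohort", "pipeline", "inputs"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        cohort=_build(CohortConfig, doc.get("cohort", {}) or {}, "cohort"),
        pipeline=_build(PipelineConfig, doc.get("pipeline", {}) or {}, "pipeline"),
        inputs=doc.get("inputs", {}) or {},
    )


def save_run_config(cfg: RunConfig, path) -> None:
    doc = {"cohort": asdict(cfg.cohort), "pipeline": asdict(cfg.pipeline),
           "inputs": cfg.inputs}
    doc["cohort"]["maf_range"] = list(doc["cohort"]["maf_range"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: dict, seeds: dict, inputs: dict,
                   timestamp: str) -> Path:
    """Record config echo, seeds, package version and input checksums."""
    from . import __version__

    doc = {
        "version": __version__,
        "timestamp": timestamp,
        "config": config,
        "seeds": seeds,
        "input_checksums": {name: sha256(p) for name, p in inputs.items()},
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return path
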
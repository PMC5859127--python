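"""End-to-end pipeline: simulate (or load) -> count -> metrics -> DE.

``run_pipeline`` drives the whole protocol comparison from a single
:class:`RunConfig` and writes machine-readable TSV/JSON reports plus a run
manifest (config snapshot, seed, version, input checksums). Reruns with an
identical config are byte-identical.

Report files written to ``outdir``:

* ``gene_models.bed12`` (+ ``.json`` sidecar) — the union-exon models
* ``counts_exonic.tsv`` / ``counts_intronic.tsv`` / ``counts_summary.tsv``
* ``qc_metrics.tsv`` — per-sample totals and exonic-read percentage
* ``read_categories.tsv`` — exonic/intronic/intergenic fractions
* ``detection_biotype.tsv`` — detection classes x biotype gene fractions
* ``expressed_biotype.tsv`` / ``read_biotype.tsv`` — per-sample biotype
  fractions of expressed genes and of counted reads
* ``usable_fractions.tsv`` — usable fractions + extra-depth requirement
* ``sample_correlation.tsv`` — sample x sample correlation
* ``concordance.tsv`` — per-biotype protocol concordance
* ``intron_rate.tsv`` / ``intron_rate_medians.tsv``
* ``de_results.tsv`` / ``de_summary_by_biotype.tsv`` /
  ``de_direction_fractions.tsv``
* ``manifest.json``
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import load_gene_models, write_gene_models_bed12
from .counting import (
    DEFAULT_MIN_OVERLAP,
    CountTable,
    GenomeIndex,
    count_samples,
    subsample_fragments,
)
from .diffexp import de_between_protocols, de_summary_by_biotype
from .fragments import read_bed12, read_sam, read_sample_sheet, write_bed12, write_sample_sheet
from .metrics import (
    biotype_expressed_gene_fractions,
    biotype_gene_fractions,
    biotype_read_fractions,
    concordance_by_biotype,
    correlation_matrix,
    detection_classes,
    expression_from_counts,
    extra_depth_required,
    intron_rate_analysis,
    merge_replicates,
    usable_fraction,
)
from .simulate import (
    generate_annotation,
    preset_config,
    sample_info_for,
    simulate_fragments,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with the comparison's defaults."""

    outdir: str = "libprep_run"
    # inputs: either simulate=True or paths to gtf + sample sheet + fragments
    simulate: bool = True
    gtf: str | None = None
    sample_sheet: str | None = None
    fragment_files: dict[str, str] = field(default_factory=dict)  # sample -> path
    # simulation scenario
    tissues: tuple[str, ...] = ("blood",)
    protocols: tuple[str, ...] = ("polyA", "riboZ")
    replicates: int = 2
    n_fragments: int = 50_000
    # thresholds (defaults as used throughout the comparison)
    min_overlap: int = DEFAULT_MIN_OVERLAP
    expressed_rpkm: float = 0.1
    corr_filter_rpkm: float = 0.5
    intron_rate_min_rpkm: float = 1.0
    fc_threshold: float = 2.0
    alpha: float = 0.05
    de_rpkm_floor: float = 0.5
    fc_flag: float = 4.0
    subsample_n: int | None = None
    stranded: bool = False
    library_size_mode: str = "counted"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_overlap", "expressed_rpkm", "corr_filter_rpkm",
                     "intron_rate_min_rpkm", "fc_threshold", "alpha",
                     "de_rpkm_floor", "fc_flag"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate:
            if not self.gtf or not self.sample_sheet:
                raise ValueError(
                    "simulate=False requires gtf and sample_sheet paths"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "protocols"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["tissues"] = list(d["tissues"])
        d["protocols"] = list(d["protocols"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full comparison; returns a summary dict (also written as
    the manifest). Fails fast on missing inputs or invalid thresholds."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    input_checksums: dict[str, str] = {}

    # ---- annotation + fragments -------------------------------------------
    if config.simulate:
        annotation = generate_annotation(seed=rng_seed)
        (outdir / "annotation.gtf").write_text(annotation.gtf_text)
        models, multi = annotation.models, annotation.multi_regions
        samples = []
        fragment_sets = {}
        sim_idx = 0
        for tissue in config.tissues:
            for protocol in config.protocols:
                for rep in range(1, config.replicates + 1):
                    sim_idx += 1
                    sample_id = f"{tissue[:1].upper()}_{'M' if protocol == 'polyA' else 'T'}_{rep}"
                    cfg = preset_config(
                        tissue, protocol, annotation,
                        n_fragments=config.n_fragments,
                        seed=rng_seed,
                    )
                    frags, _labels = simulate_fragments(
                        annotation, protocol, cfg,
                        seed=rng_seed * 1000 + sim_idx,
                        fragment_prefix=f"{sample_id}_",
                    )
                    fragment_sets[sample_id] = frags
                    samples.append(
                        sample_info_for(sample_id, tissue, protocol, rep, cfg)
                    )
        write_sample_sheet(samples, outdir / "sample_sheet.tsv")
        for sid, frags in fragment_sets.items():
            write_bed12(frags, outdir / f"fragments_{sid}.bed12")
    else:
        gtf = Path(config.gtf)
        sheet = Path(config.sample_sheet)
        for p in [gtf, sheet, *map(Path, config.fragment_files.values())]:
            if not p.exists():
                raise FileNotFoundError(f"input not found: {p}")
            input_checksums[str(p)] = _sha256(p)
        models, multi = load_gene_models(gtf, stranded_overlap=config.stranded)
        samples = read_sample_sheet(sheet)
        fragment_sets = {}
        for s in samples:
            path = Path(config.fragment_files[s.sample_id])
            reader = read_sam if path.suffix in (".sam", ".bam") else read_bed12
            fragment_sets[s.sample_id] = reader(path)

    write_gene_models_bed12(models, outdir / "gene_models.bed12")
    model_map = {m.gene_id: m for m in models}
    categories = pd.Series({m.gene_id: m.category for m in models})

    if config.subsample_n is not None:
        fragment_sets = {
            sid: subsample_fragments(frags, config.subsample_n,
                                     seed=rng_seed * 1000 + 999 + i)
            for i, (sid, frags) in enumerate(sorted(fragment_sets.items()))
        }

    # ---- counting ----------------------------------------------------------
    index = GenomeIndex(models, multi, stranded=config.stranded)
    ct = count_samples(fragment_sets, index, samples, config.min_overlap)
    ct.to_tsv(outdir)

    qc = ct.summary.copy()
    qc["exonic_pct"] = ct.exonic_read_percent().round(2)
    qc["usable_fraction"] = ct.usable_fraction().round(4)
    qc.to_csv(outdir / "qc_metrics.tsv", sep="\t")

    cat_frac = ct.summary[["exonic", "intronic", "intergenic"]].div(
        ct.summary["unique_fragments"], axis=0
    )
    cat_frac.to_csv(outdir / "read_categories.tsv", sep="\t")

    # ---- expression + merged conditions ------------------------------------
    by_sample = {s.sample_id: s for s in samples}
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(f"{s.tissue}_{s.protocol}", []).append(s.sample_id)
    merged = merge_replicates(ct, groups)
    expr = expression_from_counts(ct.exonic, model_map)
    expr_merged = expression_from_counts(merged.exonic, model_map)

    if expr.cpm.shape[1] >= 2:
        try:
            corr = correlation_matrix(expr, config.corr_filter_rpkm)
            corr.to_csv(outdir / "sample_correlation.tsv", sep="\t")
        except ValueError as exc:
            logger.warning("sample correlation skipped: %s", exc)

    # ---- per-tissue protocol comparisons -----------------------------------
    usable_rows = []
    manifest_metrics: dict[str, Any] = {}
    det_tables, conc_tables, ir_written = [], [], False
    for tissue in sorted({s.tissue for s in samples}):
        g_polya = f"{tissue}_polyA"
        g_riboz = f"{tissue}_riboZ"
        if g_polya not in groups or g_riboz not in groups:
            continue
        det = detection_classes(
            expr_merged.rpkm[g_polya], expr_merged.rpkm[g_riboz],
            config.expressed_rpkm,
        )
        tab = biotype_gene_fractions(det, categories)
        tab.insert(0, "tissue", tissue)
        det_tables.append(tab)

        frac_p = float(usable_fraction(
            merged.exonic[g_polya].sum(),
            merged.summary.loc[g_polya, "total_sequenced_reads"],
        ))
        frac_r = float(usable_fraction(
            merged.exonic[g_riboz].sum(),
            merged.summary.loc[g_riboz, "total_sequenced_reads"],
        ))
        reported, raw = extra_depth_required(frac_p, frac_r)
        usable_rows.append((tissue, frac_p, frac_r, reported, raw))
        manifest_metrics[f"extra_depth_pct_{tissue}"] = reported

        conc, _flags = concordance_by_biotype(
            expr_merged.cpm[g_polya], expr_merged.cpm[g_riboz],
            categories, config.fc_flag,
        )
        conc.insert(0, "tissue", tissue)
        conc_tables.append(conc)

        de = de_between_protocols(
            ct.exonic, groups[g_polya], groups[g_riboz],
            pd.Series({g: model_map[g].exonic_length_bp for g in ct.genes}),
            fc_threshold=config.fc_threshold, alpha=config.alpha,
            rpkm_floor=config.de_rpkm_floor,
        )
        de.to_csv(outdir / "de_results.tsv", sep="\t")
        expressed = det != "None"
        tab_b, tab_c = de_summary_by_biotype(de, categories, expressed)
        tab_b.to_csv(outdir / "de_summary_by_biotype.tsv", sep="\t")
        tab_c.to_csv(outdir / "de_direction_fractions.tsv", sep="\t")
        manifest_metrics[f"n_de_{tissue}"] = int(de["is_de"].sum())

    if det_tables:
        pd.concat(det_tables).to_csv(outdir / "detection_biotype.tsv", sep="\t")
    if conc_tables:
        pd.concat(conc_tables).to_csv(outdir / "concordance.tsv", sep="\t")
    pd.DataFrame(
        usable_rows,
        columns=["tissue", "usable_polyA", "usable_riboZ",
                 "extra_depth_pct", "extra_depth_raw_pct"],
    ).to_csv(outdir / "usable_fractions.tsv", sep="\t", index=False)

    biotype_expressed_gene_fractions(
        expr.rpkm, categories, config.expressed_rpkm
    ).to_csv(outdir / "expressed_biotype.tsv", sep="\t")
    biotype_read_fractions(ct.exonic, categories).to_csv(
        outdir / "read_biotype.tsv", sep="\t"
    )

    ir = intron_rate_analysis(ct, model_map, expr.rpkm,
                              config.intron_rate_min_rpkm)
    ir.rates.round(6).to_csv(outdir / "intron_rate.tsv", sep="\t")
    ir.medians.round(6).to_csv(outdir / "intron_rate_medians.tsv", sep="\t")
    manifest_metrics["median_intron_rate"] = {
        s: {c: (None if pd.isna(v) else round(float(v), 4))
            for c, v in row.items()}
        for s, row in ir.medians.iterrows()
    }

    manifest = {
        "libprep_version": __version__,
        "seed": rng_seed,
        "config": config.to_dict(),
        "input_checksums": input_checksums,
        "n_genes": len(models),
        "samples": sorted(fragment_sets),
        "metrics": manifest_metrics,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
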
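"""End-to-end pipeline orchestration with a single declarative config.

Stages run in order scan -> genotypes -> screen -> enrich -> annotate -> pca,
each independently skippable (a stage runs when its inputs are configured).
Every run writes a manifest recording the config hash, the seed and
per-stage row counts, so results are reproducible and every irreducible
constant (FDR level, catalog thresholds) is visible in the output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .catalog import CatalogConfig, scan_reference
from .genotypes import FilterConfig, POPULATIONS, read_genotype_table
from .screen import EBMLScreen, ScreenConfig

_KNOWN_KEYS = {
    "fasta", "calls", "features", "genome", "category_files", "out_dir",
    "populations", "catalog", "filter", "screen", "pca", "seed",
}


@dataclass
class PipelineConfig:
    fasta: str | None = None
    calls: str | None = None
    features: str | None = None
    genome: str | None = None
    category_files: dict = field(default_factory=dict)
    out_dir: str = "ebml_out"
    populations: tuple = POPULATIONS
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    pca: dict = field(default_factory=lambda: {"k": 10, "encoding": "length-sum"})
    seed: int = 0

    def normalized(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = list(self.populations)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.normalized(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _coerce_section(cls, mapping: dict, section: str):
    fields = {f.name: f.type for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    coerced = {}
    for k, v in mapping.items():
        try:
            default = getattr(cls(), k)
            if isinstance(default, bool):
                coerced[k] = bool(v)
            elif isinstance(default, int):
                coerced[k] = int(v)
            elif isinstance(default, float):
                coerced[k] = float(v)
            else:
                coerced[k] = v
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bad value for {section}.{k}: {v!r}") from exc
    return cls(**coerced)


def validate_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config, fill defaults, reject unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown key(s) {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    screen_raw = dict(raw.get("screen", {}))
    screen_raw.setdefault("seed", seed)
    cfg = PipelineConfig(
        fasta=raw.get("fasta"),
        calls=raw.get("calls"),
        features=raw.get("features"),
        genome=raw.get("genome"),
        category_files=dict(raw.get("category_files", {})),
        out_dir=str(raw.get("out_dir", "ebml_out")),
        populations=tuple(raw.get("populations", POPULATIONS)),
        catalog=_coerce_section(CatalogConfig, dict(raw.get("catalog", {})), "catalog"),
        filter=_coerce_section(FilterConfig, dict(raw.get("filter", {})), "filter"),
        screen=_coerce_section(ScreenConfig, screen_raw, "screen"),
        pca=dict(raw.get("pca", {"k": 10, "encoding": "length-sum"})),
        seed=seed,
    )
    for name in ("fasta", "calls", "features", "genome"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config path '{name}' does not exist: {p}")
    return cfg


def run_pipeline(cfg: PipelineConfig, logger: logging.Logger | None = None) -> dict:
    """Run all configured stages; returns the manifest (also written to
    ``out_dir/manifest.json``)."""
    logger = logger or logging.getLogger("ebml")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "alpha": cfg.screen.alpha, "stages": {}}

    if cfg.fasta:
        catalog = scan_reference(cfg.fasta, cfg.catalog,
                                 out_path=out / "catalog.tsv", logger=logger)
        manifest["stages"]["scan"] = {"n_loci": len(catalog)}

    if cfg.calls:
        calls = read_genotype_table(cfg.calls, populations=cfg.populations)
        manifest["stages"]["genotypes"] = {"n_calls": len(calls)}
        model = EBMLScreen(calls, populations=cfg.populations,
                           filter_config=cfg.filter, config=cfg.screen)
        res = model.fit(logger=logger)
        res.to_tsv(out)
        manifest["stages"]["screen"] = {
            "n_screens": len(res.screens),
            "tested": {pair: len(df) for pair, df in sorted(res.screens.items())},
            "rejected": {pair: int(df["reject"].sum())
                         for pair, df in sorted(res.screens.items())},
            "ebml": {pop: len(s) for pop, s in sorted(res.ebml_sets.items())},
            "ebml_union": len(res.ebml_union),
        }

        if cfg.features:
            from .annotation import assign_regions, overlapping_genes, read_features
            feats = read_features(cfg.features)
            loci_frame = _loci_frame_from_ids(sorted(
                res.filtered_calls["locus_id"].unique()))
            regions = assign_regions(loci_frame, feats)
            regions.to_csv(out / "regions.tsv", sep="\t")
            genes = overlapping_genes(loci_frame, feats)
            ebml_union = res.ebml_union
            for pop, loci in sorted(res.ebml_sets.items()):
                sub = sorted(set(genes.loc[genes["locus_id"].isin(loci), "gene_id"]))
                pd.Series(sub, name="gene_id").to_csv(
                    out / f"genes_{pop}.tsv", sep="\t", index=False)
            manifest["stages"]["annotate"] = {"n_features": len(feats),
                                              "n_gene_links": len(genes)}

        if cfg.category_files:
            from .enrichment import category_enrichment
            results = {}
            universe = pd.Index(sorted(res.screen_table()["locus_id"].unique()))
            ebml_flags = pd.Series(
                [l in res.ebml_union for l in universe], index=universe)
            for name, path in sorted(cfg.category_files.items()):
                members = set(pd.read_csv(path, sep="\t", header=None)[0].astype(str))
                cat_flags = pd.Series([l in members for l in universe],
                                      index=universe)
                r = category_enrichment(ebml_flags, cat_flags, universe=universe)
                results[name] = {"chi2": r.chi2, "p_value": r.p_value,
                                 "odds_ratio": r.odds_ratio,
                                 "direction": r.direction}
            with open(out / "enrichment.json", "w") as fh:
                json.dump(results, fh, indent=2, sort_keys=True)
            manifest["stages"]["enrich"] = {"n_categories": len(results)}

        if cfg.pca:
            from .pca import MicrosatellitePCA
            k = int(cfg.pca.get("k", 10))
            pca_res = MicrosatellitePCA(
                res.filtered_calls,
                encoding=cfg.pca.get("encoding", "length-sum")).fit(k=k)
            pca_res.coordinates().to_csv(out / "pca_coordinates.tsv",
                                         sep="\t", index=False)
            pd.Series(pca_res.eigenvalues, name="eigenvalue").to_csv(
                out / "pca_eigenvalues.tsv", sep="\t", index=False)
            manifest["stages"]["pca"] = {
                "k": int(len(pca_res.eigenvalues)),
                "encoding": pca_res.encoding}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _loci_frame_from_ids(locus_ids) -> pd.DataFrame:
    """Parse 'chrom:start-end' locus ids back into coordinates where
    possible; ids without coordinates keep chrom='unknown'."""
    rows = []
    for lid in locus_ids:
        chrom, start, end = "unknown", 0, 1
        if ":" in lid and "-" in lid.rsplit(":", 1)[-1]:
            c, span = lid.rsplit(":", 1)
            s, e = span.split("-", 1)
            try:
                chrom, start, end = c, int(s), int(e)
            except ValueError:
                pass
        rows.append({"locus_id": lid, "chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows)
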
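"""Orchestration: structure -> inversions -> SNPs -> SSRs -> indels on a
genotype set, gathered into one MarkerReport.

Inversions are detected before SNPs and their core columns are masked from
SNP calling; otherwise every base of an inverted core would be re-counted
as a substitution. The pipeline itself has no randomness: identical inputs
and configuration yield byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DataError, UsageError
from .io import (
    AlignmentMatrix,
    FeatureTable,
    GenomeRecord,
    read_alignment,
    read_features_gff3,
    read_genomes,
    write_reports,
)
from .microstructure import (
    IndelEvent,
    Inversion,
    detect_inversions,
    extract_indels,
    filter_ssr_indels,
    indel_size_spectrum,
)
from .snps import Snp, SpectrumTable, call_snps, count_site_classes, substitution_spectrum
from .ssr import SsrLocus, SsrPolymorphism, compare_ssrs, detect_ssrs, DEFAULT_THRESHOLDS
from .structure import QuadripartiteStructure, detect_quadripartite

log = logging.getLogger(__name__)

DEFAULTS = {
    "format": "fasta",
    "min_ir_len": 1000,
    "seed_k": 25,
    "thresholds": DEFAULT_THRESHOLDS,
    "compound_max_gap": 100,
    "inversion_min_len": 2,
    "inversion_max_len": 100,
    "flank_window": 30,
    "min_stem": 6,
}


@dataclass
class MarkerReport:
    """Every marker inventory of one run; each summary count is re-derivable
    from the event lists carried alongside it."""

    genotype_ids: list[str]
    reference: str
    genomes: dict[str, GenomeRecord]
    structures: dict[str, QuadripartiteStructure]
    snps: list[Snp]
    spectrum: SpectrumTable
    site_classes: tuple[int, int]
    ssr_loci: dict[str, list[SsrLocus]]
    ssr_polymorphisms: list[SsrPolymorphism]
    common_indels: list[IndelEvent]
    ssr_indels: list[IndelEvent]
    indel_sizes: dict[int, int]
    indel_regions: dict[str, int]
    inversions: list[Inversion]
    config: dict = field(default_factory=dict)

    def summary_rows(self) -> list[list]:
        rows: list[list] = []
        rows.append(["n_genotypes", len(self.genotype_ids)])
        rows.append(["reference", self.reference])
        rows.append(["variable_sites", self.site_classes[0]])
        rows.append(["parsimony_informative_sites", self.site_classes[1]])
        rows.append(["snps_total", len(self.snps)])
        for cls, cnt in self.spectrum.counts.items():
            rows.append([f"snps_{cls}", cnt])
        rows.append(["snps_transitions", self.spectrum.ts_total])
        rows.append(["snps_transversions", self.spectrum.tv_total])
        rows.append(["snps_multiallelic", self.spectrum.multiallelic])
        ratio = self.spectrum.tv_ts_ratio
        rows.append(["tv_ts_ratio", "NA" if ratio is None else f"{ratio:.4f}"])
        region_counts: dict[str, int] = {}
        for s in self.snps:
            region_counts[s.region] = region_counts.get(s.region, 0) + 1
        for r in sorted(region_counts):
            rows.append([f"snps_in_{r}", region_counts[r]])
        ref_loci = self.ssr_loci[self.reference]
        rows.append(["ssrs_reference", len(ref_loci)])
        by_unit: dict[int, int] = {}
        by_region: dict[str, int] = {}
        by_ctx: dict[str, int] = {}
        for loc in ref_loci:
            by_unit[loc.unit_len] = by_unit.get(loc.unit_len, 0) + 1
            if loc.region:
                by_region[loc.region] = by_region.get(loc.region, 0) + 1
            if loc.context[0]:
                by_ctx[loc.context[0]] = by_ctx.get(loc.context[0], 0) + 1
        for k in sorted(by_unit):
            rows.append([f"ssrs_unit{k}", by_unit[k]])
        for r in sorted(by_region):
            rows.append([f"ssrs_in_{r}", by_region[r]])
        for c in sorted(by_ctx):
            rows.append([f"ssrs_{c}", by_ctx[c]])
        for gid in self.genotype_ids:
            rows.append([f"ssrs_{gid}", len(self.ssr_loci[gid])])
        rows.append(
            ["ssr_loci_compared", len(self.ssr_polymorphisms)]
        )
        rows.append(
            ["ssr_polymorphic_loci",
             sum(p.is_polymorphic for p in self.ssr_polymorphisms)]
        )
        rows.append(["common_indels", len(self.common_indels)])
        rows.append(["ssr_related_indels", len(self.ssr_indels)])
        if self.indel_sizes:
            rows.append(["indel_max_bp", max(self.indel_sizes)])
            modal = max(self.indel_sizes.items(), key=lambda kv: (kv[1], -kv[0]))
            rows.append(["indel_modal_bp", modal[0]])
        for r in sorted(self.indel_regions):
            rows.append([f"indels_in_{r}", self.indel_regions[r]])
        rows.append(["inversions", len(self.inversions)])
        for k, inv in enumerate(self.inversions):
            rows.append(
                [f"inversion{k}",
                 f"core={inv.length}bp,stem={inv.flank_repeat_len}bp,"
                 f"in={'|'.join(sorted(inv.inverted_genotypes))}"]
            )
        return rows


def load_config(path: str | Path) -> dict:
    """Plain key=value configuration; comma-separated lists; '#' comments."""
    cfg: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise UsageError(f"bad config line (expected key=value): {raw!r}")
        key, value = (x.strip() for x in line.split("=", 1))
        cfg[key] = value
    return cfg


def _as_int_tuple(value) -> tuple[int, ...]:
    if isinstance(value, str):
        return tuple(int(x) for x in value.replace(",", " ").split())
    return tuple(int(x) for x in value)


def analyze(
    genomes: dict[str, GenomeRecord],
    aln: AlignmentMatrix,
    reference: str | None = None,
    features: FeatureTable | None = None,
    config: dict | None = None,
) -> MarkerReport:
    """Run every detector on an in-memory genome set + alignment."""
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    if not genomes:
        raise UsageError("empty genotype set")
    ids = sorted(genomes)
    if reference is None:
        reference = ids[0]
        log.warning(
            "no reference genotype configured; defaulting to the "
            "lexicographically first id %r", reference
        )
    if reference not in genomes:
        raise UsageError(f"reference {reference!r} not among genomes {ids}")
    if features is None and genomes[reference].features is not None:
        features = genomes[reference].features

    structures = {
        gid: detect_quadripartite(
            genomes[gid], min_ir_len=int(cfg["min_ir_len"]), seed_k=int(cfg["seed_k"])
        )
        for gid in ids
    }
    ref_struct = structures[reference]
    if ref_struct.has_ir and not ref_struct.input_is_canonical_order:
        raise DataError(
            f"reference {reference!r} is not in canonical LSC-IRb-SSC-IRa "
            "order; canonicalize the genomes and realign before analysis"
        )

    thresholds = _as_int_tuple(cfg["thresholds"])
    inversions = detect_inversions(
        aln,
        reference,
        min_len=int(cfg["inversion_min_len"]),
        max_len=int(cfg["inversion_max_len"]),
        flank_window=int(cfg["flank_window"]),
        min_stem=int(cfg["min_stem"]),
        structure=ref_struct,
        features=features,
    )
    masked = {
        c for inv in inversions for c in range(inv.aln_span[0], inv.aln_span[1])
    }
    snps = call_snps(
        aln, ref_struct, reference, features=features, exclude_cols=masked
    )
    spectrum = substitution_spectrum(snps)
    site_classes = count_site_classes(aln)

    gap = cfg["compound_max_gap"]
    gap = None if gap in (None, "none", "None") else int(gap)
    ssr_loci = {
        gid: detect_ssrs(
            genomes[gid],
            thresholds=thresholds,
            compound_max_gap=gap,
            structure=structures[gid],
            features=features if gid == reference else None,
        )
        for gid in ids
    }
    polymorphisms = compare_ssrs(ssr_loci, aln, genomes)

    indels = extract_indels(aln, reference, structure=ref_struct, features=features)
    common, ssr_related = filter_ssr_indels(indels, ssr_loci, aln)
    sizes, regions = indel_size_spectrum(common)

    return MarkerReport(
        genotype_ids=ids,
        reference=reference,
        genomes=genomes,
        structures=structures,
        snps=snps,
        spectrum=spectrum,
        site_classes=site_classes,
        ssr_loci=ssr_loci,
        ssr_polymorphisms=polymorphisms,
        common_indels=common,
        ssr_indels=ssr_related,
        indel_sizes=sizes,
        indel_regions=regions,
        inversions=inversions,
        config={k: str(v) for k, v in cfg.items()} | {"reference": reference},
    )


def run_pipeline(config: dict | str | Path) -> tuple[MarkerReport, dict[str, Path]]:
    """Execute the whole pipeline from a configuration mapping or file.

    Recognised keys: genomes (comma-separated paths), format (fasta|genbank),
    alignment, features (GFF3, optional), reference, out, plus the detector
    parameters in DEFAULTS. Every effective parameter is logged and recorded
    in the report for reproducibility.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    paths = cfg.get("genomes")
    if not paths:
        raise UsageError("config must name at least one genome file (genomes=)")
    if isinstance(paths, str):
        paths = [p.strip() for p in paths.split(",") if p.strip()]
    if "alignment" not in cfg:
        raise UsageError("config must name the alignment file (alignment=)")
    genomes = read_genomes(paths, format=cfg.get("format", "fasta"))
    aln = read_alignment(cfg["alignment"], genomes)
    reference = cfg.get("reference")
    features = None
    if cfg.get("features"):
        ref_for_len = genomes[reference] if reference else genomes[sorted(genomes)[0]]
        features = read_features_gff3(cfg["features"], ref_for_len)
    report = analyze(
        genomes, aln, reference=reference, features=features,
        config={k: v for k, v in cfg.items() if k in DEFAULTS},
    )
    for key, value in report.config.items():
        log.info("parameter %s = %s", key, value)
    written: dict[str, Path] = {}
    if cfg.get("out"):
        written = write_reports(report, cfg["out"])
    return report, written
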
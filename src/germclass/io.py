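"""Readers and writers for the external formats, run configuration and the
run manifest.

Formats: case genotypes as VCF (via pysam, multi-allelic records split and
normalized); control panels, annotations, ClinVar tables and results as
TSV; the repeat mask as BED (0-based half-open on disk, 1-based inclusive
in memory).  Every reader returns typed objects plus explicit rejection
records for malformed rows — bad rows are logged, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
import yaml
from intervaltree import IntervalTree

from .classifier import ClassificationResult, PatientSummary
from .clinvar import (
    ClinVarRecord,
    parse_review_status,
    parse_significance,
)
from .population import CohortSiteTable
from .variants import (
    Consequence,
    GenomicVariant,
    InvalidVariantError,
    MutationTasterCall,
    PolyPhenCall,
    PredictionScores,
    ProteinChange,
    ProteinChangeParseError,
    SiftCall,
    Thresholds,
    VariantAnnotation,
    normalize_variant,
    parse_protein_change,
)

__all__ = [
    "RejectedRow",
    "RunConfig",
    "read_case_vcf",
    "write_case_vcf",
    "read_control_panel",
    "write_control_panel",
    "read_clinvar_table",
    "write_clinvar_table",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_repeat_bed",
    "write_repeat_bed",
    "read_condition_allowlist",
    "write_results",
    "read_results",
    "write_patient_summaries",
    "write_manifest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RejectedRow:
    source: str
    row: int
    reason: str


class VcfFormatError(ValueError):
    """Fatal VCF problem, with record context."""


# ---------------------------------------------------------------------------
# case VCF


def read_case_vcf(
    path: str | Path, cohort_name: str = "case"
) -> tuple[CohortSiteTable, dict[GenomicVariant, dict[str, str]]]:
    """Read genotypes into a site table plus per-patient carrier maps.

    AC counts alternate alleles over called genotypes; AN is twice the
    number of called diploid genotypes (missing genotypes are excluded).
    Multi-allelic records are split into normalized biallelic variants.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    records: list[tuple[GenomicVariant, int, int]] = []
    carriers: dict[GenomicVariant, dict[str, str]] = {}
    for rec in vcf:
        if rec.alts is None:
            continue
        for alt_index, alt in enumerate(rec.alts, start=1):
            try:
                raw = GenomicVariant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
            except InvalidVariantError as exc:
                raise VcfFormatError(
                    f"{path}:{rec.chrom}:{rec.pos}: {exc}"
                ) from exc
            variant = normalize_variant(raw)
            ac = an = 0
            carrier_map: dict[str, str] = {}
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                an += len(gt)
                n_alt = sum(a == alt_index for a in gt)
                ac += n_alt
                if n_alt == len(gt):
                    carrier_map[sample] = "hom"
                elif n_alt:
                    carrier_map[sample] = "het"
            if an == 0:
                logger.warning("site %s has no called genotypes; skipped", variant)
                continue
            records.append((variant, ac, an))
            carriers[variant] = carrier_map
    table = CohortSiteTable(cohort_name, records, default_diploid_n=len(samples))
    return table, carriers


def write_case_vcf(
    path: str | Path,
    patients: Sequence[str],
    carriers: Mapping[GenomicVariant, Mapping[str, str]],
    case_table: CohortSiteTable,
) -> None:
    """Write a plain-text VCF with one column per patient (GT only)."""
    variants = sorted(case_table.records)
    contigs = sorted({v.contig for v in variants})
    lines = ["##fileformat=VCFv4.2"]
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(patients)
    )
    for v in variants:
        carrier_map = carriers.get(v, {})
        gts = []
        for p in patients:
            zyg = carrier_map.get(p)
            gts.append({"het": "0/1", "hom": "1/1", None: "0/0"}[zyg])
        lines.append(
            f"{v.contig}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# control panels (site-frequency TSV)

_PANEL_COLUMNS = ["contig", "position", "ref", "alt", "ac", "an"]


def read_control_panel(
    path: str | Path,
    cohort_name: Optional[str] = None,
    default_diploid_n: Optional[int] = None,
) -> tuple[CohortSiteTable, list[RejectedRow]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    table = CohortSiteTable(
        cohort_name or path.stem, default_diploid_n=default_diploid_n
    )
    rejections = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            variant = GenomicVariant(
                row.contig, int(row.position), row.ref.upper(), row.alt.upper()
            )
            table.add(variant, int(row.ac), int(row.an))
        except (ValueError, AttributeError) as exc:
            logger.warning("%s row %d rejected: %s", path, i, exc)
            rejections.append(RejectedRow(str(path), i, str(exc)))
    return table, rejections


def write_control_panel(path: str | Path, table: CohortSiteTable) -> None:
    rows = [
        {
            "contig": v.contig,
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "ac": ac,
            "an": an,
        }
        for v, (ac, an) in sorted(table.records.items())
    ]
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ClinVar-style table

_CLINVAR_COLUMNS = [
    "contig", "position", "ref", "alt", "gene", "significance",
    "review_status", "conditions", "consequence", "protein_changes",
]


def _encode_changes(changes: Iterable[ProteinChange]) -> str:
    parts = [f"{c.transcript}:{c.hgvs_p()}" for c in changes]
    return "|".join(parts) or "."


def _decode_changes(text: str, gene: str) -> tuple[ProteinChange, ...]:
    if not text or text == ".":
        return ()
    changes = []
    for part in text.split("|"):
        transcript, _, hgvs = part.rpartition(":")
        changes.append(parse_protein_change(hgvs, gene=gene, transcript=transcript))
    return tuple(changes)


def read_clinvar_table(
    path: str | Path,
) -> tuple[list[ClinVarRecord], list[RejectedRow]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    missing = set(_CLINVAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records, rejections = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                ClinVarRecord(
                    variant=GenomicVariant(
                        row.contig, int(row.position), row.ref.upper(), row.alt.upper()
                    ),
                    gene=row.gene,
                    significance=parse_significance(row.significance),
                    review_status=parse_review_status(row.review_status),
                    conditions=frozenset(
                        c for c in row.conditions.split("|") if c and c != "."
                    ),
                    consequence=Consequence(row.consequence),
                    protein_changes=_decode_changes(row.protein_changes, row.gene),
                )
            )
        except (ValueError, AttributeError) as exc:
            logger.warning("%s row %d rejected: %s", path, i, exc)
            rejections.append(RejectedRow(str(path), i, str(exc)))
    return records, rejections


def write_clinvar_table(path: str | Path, records: Iterable[ClinVarRecord]) -> None:
    rows = [
        {
            "contig": r.variant.contig,
            "position": r.variant.position,
            "ref": r.variant.ref,
            "alt": r.variant.alt,
            "gene": r.gene,
            "significance": r.significance.value,
            "review_status": r.review_status.value,
            "conditions": "|".join(sorted(r.conditions)) or ".",
            "consequence": r.consequence.value,
            "protein_changes": _encode_changes(r.protein_changes),
        }
        for r in sorted(records, key=lambda r: (r.variant, r.gene))
    ]
    pd.DataFrame(rows, columns=_CLINVAR_COLUMNS).to_csv(path, sep="\t", index=False)


_CLINVAR_VCF_CONSEQUENCES = {
    "nonsense": Consequence.STOPGAIN,
    "missense_variant": Consequence.NONSYNONYMOUS_SNV,
    "splice_donor_variant": Consequence.SPLICE_SITE,
    "splice_acceptor_variant": Consequence.SPLICE_SITE,
    "frameshift_variant": Consequence.FRAMESHIFT_DELETION,
    "inframe_deletion": Consequence.NONFRAMESHIFT_DELETION,
    "inframe_insertion": Consequence.NONFRAMESHIFT_INSERTION,
    "stop_lost": Consequence.STOPLOSS,
    "initiator_codon_variant": Consequence.STARTLOSS,
    "synonymous_variant": Consequence.SYNONYMOUS,
}


def convert_clinvar_vcf(path: str | Path) -> tuple[list[ClinVarRecord], list[RejectedRow]]:
    """Best-effort converter from a real ClinVar VCF export to records.

    Reads CLNSIG / CLNREVSTAT / CLNDN / GENEINFO / MC INFO fields; rows it
    cannot interpret become rejection records.  Provided for convenience —
    the pipeline's native input is the tabular format of
    :func:`read_clinvar_table`.
    """
    records, rejections = [], []
    vcf = pysam.VariantFile(str(path))
    for i, rec in enumerate(vcf, start=1):
        try:
            info = rec.info

            def text(key):
                value = info.get(key)
                if value is None:
                    return ""
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                return str(value)

            gene = text("GENEINFO").split(":", 1)[0]
            if not gene or not rec.alts:
                raise ValueError("no gene symbol or alt allele")
            consequence = Consequence.OTHER
            for token in text("MC").replace(",", "|").split("|"):
                if token in _CLINVAR_VCF_CONSEQUENCES:
                    consequence = _CLINVAR_VCF_CONSEQUENCES[token]
                    break
            conditions = frozenset(
                c.replace("_", " ")
                for c in text("CLNDN").split("|")
                if c and c not in ("not_provided", "not_specified")
            )
            records.append(
                ClinVarRecord(
                    variant=GenomicVariant(
                        rec.chrom, rec.pos, rec.ref.upper(), rec.alts[0].upper()
                    ),
                    gene=gene,
                    significance=parse_significance(text("CLNSIG").replace("_", " ")),
                    review_status=parse_review_status(
                        text("CLNREVSTAT").replace("_", " ")
                    ),
                    conditions=conditions,
                    consequence=consequence,
                )
            )
        except (ValueError, KeyError) as exc:
            rejections.append(RejectedRow(str(path), i, str(exc)))
    return records, rejections


# ---------------------------------------------------------------------------
# annotation TSV

_ANNOTATION_COLUMNS = [
    "contig", "position", "ref", "alt", "gene", "consequence",
    "protein_changes", "revel", "cadd_phred", "sift", "polyphen_hdiv",
    "polyphen_hvar", "mutationtaster",
]


def _call(value: str, enum):
    return None if value in (".", "") else enum(value)


def read_annotation_tsv(
    path: str | Path,
    repeat_mask: Optional[Mapping[str, IntervalTree]] = None,
) -> tuple[dict[GenomicVariant, VariantAnnotation], list[RejectedRow]]:
    """Typed annotations keyed by normalized variant.

    ``repeat_mask`` (from :func:`read_repeat_bed`) resolves each variant's
    ``in_repeat_region``; without it all variants are outside repeats.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    annotations: dict[GenomicVariant, VariantAnnotation] = {}
    rejections = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            variant = normalize_variant(
                GenomicVariant(
                    row.contig, int(row.position), row.ref.upper(), row.alt.upper()
                )
            )
            changes = _decode_changes(row.protein_changes, row.gene)
            if row.revel in (".", ""):
                revel: tuple[tuple[ProteinChange, float], ...] = ()
            else:
                scores = [float(s) for s in row.revel.split("|")]
                if len(scores) != len(changes):
                    raise ValueError(
                        f"{len(scores)} REVEL scores for {len(changes)} protein changes"
                    )
                revel = tuple(zip(changes, scores))
            scores_obj = PredictionScores(
                revel_per_change=revel,
                cadd_phred=(
                    None if row.cadd_phred in (".", "") else float(row.cadd_phred)
                ),
                sift_call=_call(row.sift, SiftCall),
                polyphen_hdiv_call=_call(row.polyphen_hdiv, PolyPhenCall),
                polyphen_hvar_call=_call(row.polyphen_hvar, PolyPhenCall),
                mutationtaster_call=_call(row.mutationtaster, MutationTasterCall),
            )
            span = range(
                variant.position, variant.position + max(len(variant.ref), 1)
            )
            in_repeat = False
            if repeat_mask and variant.contig in repeat_mask:
                tree = repeat_mask[variant.contig]
                in_repeat = any(tree.overlap(span.start, span.stop))
            annotations[variant] = VariantAnnotation(
                variant=variant,
                gene=row.gene,
                consequence=Consequence(row.consequence),
                protein_changes=changes,
                in_repeat_region=in_repeat,
                scores=scores_obj,
            )
        except (ValueError, AttributeError, ProteinChangeParseError) as exc:
            logger.warning("%s row %d rejected: %s", path, i, exc)
            rejections.append(RejectedRow(str(path), i, str(exc)))
    return annotations, rejections


def write_annotation_tsv(
    path: str | Path, annotations: Iterable[VariantAnnotation]
) -> None:
    rows = []
    for a in sorted(annotations, key=lambda a: a.variant):
        revel = {c: s for c, s in a.scores.revel_per_change}
        revel_text = (
            "|".join(f"{revel[c]:.3f}" for c in a.protein_changes)
            if revel and all(c in revel for c in a.protein_changes)
            else "."
        )
        rows.append(
            {
                "contig": a.variant.contig,
                "position": a.variant.position,
                "ref": a.variant.ref,
                "alt": a.variant.alt,
                "gene": a.gene,
                "consequence": a.consequence.value,
                "protein_changes": _encode_changes(a.protein_changes),
                "revel": revel_text,
                "cadd_phred": (
                    "." if a.scores.cadd_phred is None else f"{a.scores.cadd_phred:g}"
                ),
                "sift": a.scores.sift_call.value if a.scores.sift_call else ".",
                "polyphen_hdiv": (
                    a.scores.polyphen_hdiv_call.value
                    if a.scores.polyphen_hdiv_call
                    else "."
                ),
                "polyphen_hvar": (
                    a.scores.polyphen_hvar_call.value
                    if a.scores.polyphen_hvar_call
                    else "."
                ),
                "mutationtaster": (
                    a.scores.mutationtaster_call.value
                    if a.scores.mutationtaster_call
                    else "."
                ),
            }
        )
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# repeat BED and allowlist


def read_repeat_bed(path: str | Path) -> dict[str, IntervalTree]:
    """BED intervals (0-based half-open) as 1-based inclusive interval trees.

    The returned trees are queried with 1-based inclusive coordinates via
    ``tree.overlap(start, end + 1)``.
    """
    trees: dict[str, IntervalTree] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: BED needs >= 3 columns")
        contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        if end0 <= start0:
            raise ValueError(f"{path}:{i}: empty interval")
        # [start0, end0) zero-based  ->  [start0+1, end0] one-based inclusive
        trees.setdefault(contig, IntervalTree()).addi(start0 + 1, end0 + 1)
    return trees


def write_repeat_bed(
    path: str | Path, intervals: Mapping[str, Sequence[tuple[int, int]]]
) -> None:
    """``intervals`` holds 1-based inclusive (start, end) pairs per contig."""
    lines = []
    for contig in sorted(intervals):
        for start1, end1 in sorted(intervals[contig]):
            lines.append(f"{contig}\t{start1 - 1}\t{end1}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_condition_allowlist(path: str | Path) -> frozenset[str]:
    conditions = {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(conditions)


# ---------------------------------------------------------------------------
# results and summaries

_FLAG_COLUMNS = ["PVS1", "PS1", "PM5", "PM4", "PP3", "PM2", "PS4", "BS1"]


def _stars(p: float, alpha: float) -> str:
    if p < alpha / 5:  # the conventional stricter level (0.01 at alpha 0.05)
        return "**"
    if p < alpha:
        return "*"
    return ""


def write_results(
    path: str | Path,
    results: Iterable[ClassificationResult],
    thresholds: Thresholds = Thresholds(),
) -> None:
    """Classification table mirroring the published per-variant layout:
    identity, gene, criterion flags, per-comparison enrichment p-values
    (starred below alpha and alpha/5) and the final class."""
    rows = []
    for r in sorted(results, key=lambda r: (r.variant, r.gene)):
        flags = r.profile.flags()
        comparisons = "|".join(
            f"{c.case_cohort}~{c.control_cohort}:{c.p_value:.3e}"
            f"{_stars(c.p_value, thresholds.ps4_alpha)}"
            f":{c.direction.value}{':interp' if c.control_an_interpolated else ''}"
            for c in r.profile.population.comparisons
        )
        rows.append(
            {
                "contig": r.variant.contig,
                "position": r.variant.position,
                "ref": r.variant.ref,
                "alt": r.variant.alt,
                "gene": r.gene,
                **{name: int(flags[name]) for name in _FLAG_COLUMNS},
                "clinvar_recorded": int(r.profile.clinvar_recorded),
                "fired_rules": "|".join(r.fired_rules) or ".",
                "class": r.klass.value,
                "comparisons": comparisons or ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})


def write_patient_summaries(
    path: str | Path, summaries: Iterable[PatientSummary]
) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "n_plp": len(s.carried_plp),
            "n_vus": len(s.carried_vus),
            "plp_variants": "|".join(
                f"{r.gene}:{r.variant}" for r in s.carried_plp
            ) or ".",
            "plp_classes": "|".join(r.klass.value for r in s.carried_plp) or ".",
            "zygosity": "|".join(
                s.zygosity[v] for v in sorted(s.zygosity)
            ) or ".",
        }
        for s in summaries
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "n_plp", "n_vus", "plp_variants", "plp_classes", "zygosity"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration and manifest


@dataclass
class RunConfig:
    """Paths and thresholds for one classification run."""

    case_vcf: Path
    annotations: Path
    clinvar: Path
    allowlist: Path
    controls: dict[str, Path]
    out_dir: Path
    extra_cases: dict[str, tuple[Path, int]] = field(default_factory=dict)
    repeat_bed: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        resolve = lambda p: (base / p).resolve() if not Path(p).is_absolute() else Path(p)
        return cls(
            case_vcf=resolve(raw["case_vcf"]),
            annotations=resolve(raw["annotations"]),
            clinvar=resolve(raw["clinvar"]),
            allowlist=resolve(raw["allowlist"]),
            controls={k: resolve(v) for k, v in raw["controls"].items()},
            extra_cases={
                k: (resolve(v["path"]), int(v["n"]))
                for k, v in raw.get("extra_cases", {}).items()
            },
            repeat_bed=resolve(raw["repeat_bed"]) if raw.get("repeat_bed") else None,
            thresholds=Thresholds(**raw.get("thresholds", {})),
            out_dir=resolve(raw.get("out_dir", "results")),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def validate(self) -> None:
        required = [
            self.case_vcf, self.annotations, self.clinvar, self.allowlist,
            *self.controls.values(), *(p for p, _ in self.extra_cases.values()),
        ]
        if self.repeat_bed is not None:
            required.append(self.repeat_bed)
        missing = [str(p) for p in required if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if len(self.controls) < 1:
            raise ValueError("at least one control panel is required")

    def input_paths(self) -> dict[str, Path]:
        paths = {
            "case_vcf": self.case_vcf,
            "annotations": self.annotations,
            "clinvar": self.clinvar,
            "allowlist": self.allowlist,
        }
        for name, p in self.controls.items():
            paths[f"control_{name}"] = p
        for name, (p, _) in self.extra_cases.items():
            paths[f"case_{name}"] = p
        if self.repeat_bed is not None:
            paths["repeat_bed"] = self.repeat_bed
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: RunConfig,
    stage_counts: Mapping[str, int],
) -> dict:
    """Machine-readable run manifest: config hash, input checksums, and the
    stage-count funnel (inputs, gated, population-tested, per-class)."""
    config_text = json.dumps(
        {
            "thresholds": {
                k: getattr(config.thresholds, k)
                for k in config.thresholds.__dataclass_fields__
            },
            "inputs": {k: str(v) for k, v in config.input_paths().items()},
            "seed": config.seed,
        },
        sort_keys=True,
    )
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "input_sha256": {
            name: _sha256(p) for name, p in sorted(config.input_paths().items())
        },
        "stage_counts": dict(stage_counts),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
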
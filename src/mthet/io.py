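"""Readers and writers for the pipeline's plain-text formats.

The core interchange format is a pileup TSV — one row per sample-position
with forward/reverse counts for the four bases (optionally mean quality per
base) — because the data model is per-position count vectors, not called
genotypes.  A VCF export of reported calls is provided as a convenience.
Report frequencies print in percent with two decimals to match the field's
table conventions; machine-readable outputs keep full precision.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import BASES, AlleleCounts, FilterConfig, VariantCall
from .classify import SLOTS, ClassifiedSite
from .reference import GENOME_LENGTH, MtReference, check_np

PILEUP_COLUMNS = ["sample_id", "np", "ref"] + [
    f"{b}_{d}" for b in BASES for d in ("fwd", "rev")
]
QUALITY_COLUMNS = [f"q_{b}" for b in BASES]
MANIFEST_COLUMNS = ["sample_id", "family_id", "role", "tissue"]


class PileupFormatError(ValueError):
    """Malformed pileup/manifest input, reported with row context."""


def read_pileup(path: str | Path) -> list[AlleleCounts]:
    """Read and validate a pileup TSV into AlleleCounts rows.

    Hard errors (with line numbers) on missing columns, negative counts,
    out-of-range positions, and duplicate (sample, position) entries.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise PileupFormatError(f"{path}: missing pileup columns {missing}")
    has_quality = all(c in df.columns for c in QUALITY_COLUMNS)
    out: list[AlleleCounts] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            np_ = int(d["np"])
            check_np(np_)
            fwd = {b: int(d[f"{b}_fwd"]) for b in BASES}
            rev = {b: int(d[f"{b}_rev"]) for b in BASES}
            quality = (
                {b: float(d[f"q_{b}"]) for b in BASES} if has_quality else None
            )
            counts = AlleleCounts(str(d["sample_id"]), np_, fwd, rev, quality)
        except (ValueError, KeyError) as exc:
            raise PileupFormatError(f"{path} line {i}: {exc}") from exc
        key = (counts.sample_id, counts.np)
        if key in seen:
            raise PileupFormatError(
                f"{path} line {i}: duplicate entry for sample {key[0]} np {key[1]}"
            )
        seen.add(key)
        out.append(counts)
    return out


def write_pileup(
    rows: Iterable[AlleleCounts] | pd.DataFrame,
    path: str | Path,
    reference: MtReference | None = None,
) -> None:
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        rows.to_csv(path, sep="\t", index=False)
        return
    reference = reference or MtReference.load()
    records = []
    for c in rows:
        rec = {"sample_id": c.sample_id, "np": c.np, "ref": reference.base(c.np)}
        for b in BASES:
            rec[f"{b}_fwd"] = c.fwd.get(b, 0)
            rec[f"{b}_rev"] = c.rev.get(b, 0)
        if c.quality is not None:
            for b in BASES:
                rec[f"q_{b}"] = c.quality.get(b, 0.0)
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[dict]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise PileupFormatError(f"{path}: missing manifest columns {missing}")
    rows = df[MANIFEST_COLUMNS].to_dict("records")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise PileupFormatError(f"{path}: duplicate sample_id {dup}")
    return rows


def write_manifest(rows: Iterable[Mapping], path: str | Path) -> None:
    pd.DataFrame(list(rows))[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def write_variant_report(calls: Iterable[VariantCall], path: str | Path) -> None:
    """TSV of calls in the table vocabulary (alleles, #For:#Rev, percents)."""
    records = []
    for c in calls:
        records.append(
            {
                "sample_id": c.sample_id,
                "np": c.np,
                "status": c.status,
                "total_coverage": c.total_coverage,
                "major_allele": c.major_allele or "",
                "major_pct": f"{100.0 * c.major_freq:.2f}",
                "minor_allele": c.minor_allele or "",
                "minor_for_rev": f"{c.minor_fwd}:{c.minor_rev}",
                "minor_pct": f"{c.minor_pct:.2f}",
            }
        )
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def write_classification_report(
    sites: Iterable[ClassifiedSite], path: str | Path, reference: MtReference | None = None
) -> None:
    """TSV with one row per classified site: label, carrier, slot percents,
    annotation, and primary-haplotype-change flag ('ND' marks non-detection)."""
    records = []
    for s in sites:
        rec = {"family_id": s.family_id, "np": s.np, "label": s.label,
               "carrier": s.carrier or ""}
        for slot in SLOTS:
            pct = s.minor_pct.get(slot)
            rec[slot + "_pct"] = "ND" if pct is None else f"{pct:.2f}"
        if s.effect is not None:
            rec["gene"] = s.effect.gene or ""
            rec["region"] = s.effect.region_category
            rec["synonymous"] = (
                "" if s.effect.synonymous is None else ("Y" if s.effect.synonymous else "N")
            )
            rec["aa_change"] = (
                f"{s.effect.ref_aa}>{s.effect.alt_aa}" if s.effect.ref_aa else ""
            )
        elif reference is not None:
            feat = reference.region_of(s.np)
            rec["gene"] = feat.name
            rec["region"] = feat.category
            rec["synonymous"] = ""
            rec["aa_change"] = ""
        rec["primary_haplotype_change"] = (
            "" if s.primary_haplotype_change is None else str(s.primary_haplotype_change)
        )
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    reference: MtReference | None = None,
) -> None:
    """Export reported calls as a minimal VCFv4.2 (contig chrM, AF in INFO)."""
    reference = reference or MtReference.load()
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chrM,length={GENOME_LENGTH},assembly=rCRS-coordinates>",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Minor variant fraction of total coverage">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total coverage">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        if not c.reported:
            continue
        ref_base = reference.base(c.np)
        alt = c.minor_allele if c.minor_allele != ref_base else c.major_allele
        if alt == ref_base:
            continue
        lines.append(
            f"chrM\t{c.np}\t.\t{ref_base}\t{alt}\t.\tPASS\t"
            f"AF={c.minor_freq:.6f};DP={c.total_coverage};SAMPLE={c.sample_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass
class RunConfig:
    """Effective run settings, serializable next to every run's outputs."""

    filters: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    pileup_path: str | None = None
    manifest_path: str | None = None
    output_dir: str | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["filters"]["excluded_positions"] = sorted(self.filters.excluded_positions)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        filt = d.pop("filters", {})
        filt["excluded_positions"] = frozenset(filt.get("excluded_positions", [310, 3107]))
        return cls(filters=FilterConfig(**filt), **d)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
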
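"""Three-way classification of heteroplasmy across mother-child quartets.

Each family contributes four samples (mother/child x buccal/blood).  At every
position where at least one of the four has a reported heteroplasmic call:

* **shared** — at least one tissue of *both* mother and child carries the
  site (any pattern with >=1 reported tissue per member);
* **differentiating** — one member carries the site in *both* tissues and the
  other member in *neither*;
* **random** — the site appears in exactly one of the four samples.

Site identity is the nucleotide position alone; the direction of the minor
variant is ignored, so a mother heteroplasmic toward the variant and a child
heteroplasmic back toward the reference still match at the same site.

"Absence" for a differentiating call is only trusted when the non-carrier's
coverage supports detection at the reporting threshold (>= 2000 reads at
default filters); otherwise the site is downgraded to *unclassifiable*.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .calling import AlleleCounts, FilterConfig, VariantCall, call_position
from .reference import MtReference, SubstitutionEffect

logger = logging.getLogger(__name__)

MOTHER_BUCCAL = "mother_buccal"
MOTHER_BLOOD = "mother_blood"
CHILD_BUCCAL = "child_buccal"
CHILD_BLOOD = "child_blood"
SLOTS = (MOTHER_BUCCAL, MOTHER_BLOOD, CHILD_BUCCAL, CHILD_BLOOD)
MOTHER_SLOTS = (MOTHER_BUCCAL, MOTHER_BLOOD)
CHILD_SLOTS = (CHILD_BUCCAL, CHILD_BLOOD)

SHARED = "shared"
DIFFERENTIATING = "differentiating"
RANDOM = "random"
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class SampleQuartet:
    """The four samples of one mother-child pair; slots may be absent."""

    family_id: str
    samples: Mapping[str, str | None]

    def __post_init__(self):
        unknown = set(self.samples) - set(SLOTS)
        if unknown:
            raise ValueError(f"unknown quartet slots {sorted(unknown)}")

    def sample(self, slot: str) -> str | None:
        return self.samples.get(slot)

    @property
    def complete(self) -> bool:
        return all(self.samples.get(s) for s in SLOTS)


@dataclass(frozen=True)
class ClassifiedSite:
    """One heteroplasmic position classified within one family."""

    family_id: str
    np: int
    label: str
    #: "mother"/"child" for differentiating and random sites, else None
    carrier: str | None
    #: minor-variant percentage per slot; None marks a non-detection
    minor_pct: Mapping[str, float | None]
    primary_haplotype_change: bool | None = None
    effect: SubstitutionEffect | None = None

    def reported_slots(self) -> tuple[str, ...]:
        return tuple(s for s in SLOTS if self.minor_pct.get(s) is not None)


@dataclass(frozen=True)
class SiteComparison:
    """Carrier tissue comparison for one differentiating site."""

    family_id: str
    np: int
    buccal_pct: float
    blood_pct: float
    fold_difference: float
    buccal_higher: bool
    #: "both<10%", "both>10%" or "mixed"
    band: str


def _pattern(calls: Mapping[str, VariantCall]) -> tuple[int, int]:
    m = sum(1 for s in MOTHER_SLOTS if calls[s].reported)
    c = sum(1 for s in CHILD_SLOTS if calls[s].reported)
    return m, c


def primary_haplotype_change(calls: Mapping[str, VariantCall]) -> bool:
    """True when mother and child consensus (major) alleles differ.

    Majors are compared tissue against tissue (buccal vs buccal, blood vs
    blood); slots without a usable consensus (zero coverage) are skipped.  If
    no same-tissue pair is available, any mother major is compared with any
    child major.
    """
    def major(slot):
        call = calls.get(slot)
        return call.major_allele if call is not None else None

    pairs = [(MOTHER_BUCCAL, CHILD_BUCCAL), (MOTHER_BLOOD, CHILD_BLOOD)]
    compared = False
    for ms, cs in pairs:
        mm, cm = major(ms), major(cs)
        if mm and cm:
            compared = True
            if mm != cm:
                return True
    if not compared:
        mothers = [major(s) for s in MOTHER_SLOTS if major(s)]
        children = [major(s) for s in CHILD_SLOTS if major(s)]
        if not mothers or not children:
            raise ValueError("no consensus alleles available on one side of the pair")
        return any(m != c for m in mothers for c in children)
    return False


def classify_site(
    family_id: str,
    np_: int,
    calls: Mapping[str, VariantCall],
    cfg: FilterConfig | None = None,
) -> ClassifiedSite | None:
    """Label one position of one family from its four call statuses.

    Returns None when no slot has a reported call.  Requires all four slots;
    the caller (``classify_dataset``) skips incomplete quartets.
    """
    cfg = cfg or FilterConfig()
    missing = [s for s in SLOTS if s not in calls]
    if missing:
        raise ValueError(f"missing quartet slots {missing} for family {family_id}")
    m, c = _pattern(calls)
    if m + c == 0:
        return None

    pct = {
        s: (calls[s].minor_pct if calls[s].reported else None) for s in SLOTS
    }
    if m >= 1 and c >= 1:
        label, carrier = SHARED, None
    elif (m, c) in ((2, 0), (0, 2)):
        label = DIFFERENTIATING
        carrier = "mother" if m == 2 else "child"
        # absence is only meaningful at coverage adequate for the reporting
        # threshold in both of the non-carrier's tissues
        absent = CHILD_SLOTS if carrier == "mother" else MOTHER_SLOTS
        floor_cov = cfg.reporting_floor_coverage
        inadequate = [s for s in absent if calls[s].total_coverage < floor_cov]
        if inadequate:
            logger.warning(
                "family %s np %d: non-carrier coverage below %.0f in %s; "
                "differentiating call downgraded to unclassifiable",
                family_id, np_, floor_cov, inadequate,
            )
            label, carrier = UNCLASSIFIABLE, None
    else:
        label = RANDOM
        carrier = "mother" if m == 1 else "child"

    return ClassifiedSite(
        family_id,
        np_,
        label,
        carrier,
        pct,
        primary_haplotype_change=primary_haplotype_change(calls),
    )


def site_comparison(site: ClassifiedSite) -> SiteComparison:
    """Buccal-blood comparison of the carrier's minor frequencies."""
    if site.label != DIFFERENTIATING or site.carrier is None:
        raise ValueError("site_comparison applies to differentiating sites")
    bu_slot, bl_slot = (
        (MOTHER_BUCCAL, MOTHER_BLOOD) if site.carrier == "mother" else (CHILD_BUCCAL, CHILD_BLOOD)
    )
    bu, bl = site.minor_pct[bu_slot], site.minor_pct[bl_slot]
    if bu is None or bl is None:
        raise ValueError("carrier must have frequencies in both tissues")
    if min(bu, bl) <= 0:
        raise ValueError(f"zero carrier frequency at np {site.np}; fold undefined")
    if bu < 10 and bl < 10:
        band = "both<10%"
    elif bu > 10 and bl > 10:
        band = "both>10%"
    else:
        band = "mixed"
    return SiteComparison(
        site.family_id,
        site.np,
        bu,
        bl,
        max(bu, bl) / min(bu, bl),
        bu > bl,
        band,
    )


@dataclass
class ClassificationResult:
    """Classified sites plus the derived per-site comparisons and tallies."""

    sites: list[ClassifiedSite]
    comparisons: list[SiteComparison]
    n_families: int
    skipped: list[tuple[str, int, str]] = field(default_factory=list)

    def by_label(self, label: str) -> list[ClassifiedSite]:
        return [s for s in self.sites if s.label == label]

    def summary(self, reference: MtReference | None = None) -> dict:
        out: dict = {"n_families": self.n_families}
        for label in (SHARED, DIFFERENTIATING, RANDOM, UNCLASSIFIABLE):
            sites = self.by_label(label)
            fams = sorted({s.family_id for s in sites})
            entry = {
                "n_families": len(fams),
                "families": fams,
                "n_sites": len(sites),
                "distinct_nps": len({s.np for s in sites}),
            }
            if label in (DIFFERENTIATING, RANDOM):
                entry["carrier"] = {
                    "mother": sum(1 for s in sites if s.carrier == "mother"),
                    "child": sum(1 for s in sites if s.carrier == "child"),
                }
            if label == RANDOM:
                tissue = {"buccal": 0, "blood": 0}
                for s in sites:
                    slot = s.reported_slots()[0]
                    tissue["buccal" if "buccal" in slot else "blood"] += 1
                entry["tissue"] = tissue
            if reference is not None:
                cr = sum(1 for s in sites if reference.in_control_region(s.np))
                entry["control_region_sites"] = cr
                entry["coding_region_sites"] = len(sites) - cr
            out[label] = entry
        if self.comparisons:
            comps = self.comparisons
            out["differentiating_comparison"] = {
                "both_below_10pct": sum(1 for c in comps if c.band == "both<10%"),
                "both_above_10pct": sum(1 for c in comps if c.band == "both>10%"),
                "mixed_band": sum(1 for c in comps if c.band == "mixed"),
                "buccal_higher": sum(1 for c in comps if c.buccal_higher),
                "fold_below_2": sum(1 for c in comps if c.fold_difference < 2),
                "fold_2_to_3": sum(1 for c in comps if 2 <= c.fold_difference <= 3),
                "fold_above_3": sum(1 for c in comps if c.fold_difference > 3),
            }
        return out


def quartets_from_manifest(manifest: Iterable[Mapping]) -> list[SampleQuartet]:
    """Build quartets from manifest rows (sample_id, family_id, role, tissue)."""
    slots: dict[str, dict[str, str]] = defaultdict(dict)
    seen_samples: set[str] = set()
    for row in manifest:
        sid, fid = str(row["sample_id"]), str(row["family_id"])
        role, tissue = row["role"], row["tissue"]
        if role not in ("mother", "child") or tissue not in ("buccal", "blood"):
            raise ValueError(f"bad manifest row for sample {sid}: {role}/{tissue}")
        if sid in seen_samples:
            raise ValueError(f"duplicate sample_id {sid} in manifest")
        seen_samples.add(sid)
        slot = f"{role}_{tissue}"
        if slot in slots[fid]:
            raise ValueError(f"family {fid} has two samples in slot {slot}")
        slots[fid][slot] = sid
    return [SampleQuartet(fid, dict(sl)) for fid, sl in sorted(slots.items())]


def classify_dataset(
    pileup: Iterable[AlleleCounts],
    manifest: Iterable[Mapping],
    cfg: FilterConfig | None = None,
    reference: MtReference | None = None,
) -> ClassificationResult:
    """Call every pileup row, then classify every candidate site per family.

    A position is a candidate for a family when any of its four samples has a
    reported call there; classification then needs call status for all four
    slots at that position (families with absent slots or missing pileup rows
    are skipped at that site, with a warning — absence cannot be certified).
    """
    cfg = cfg or FilterConfig()
    quartets = quartets_from_manifest(manifest)

    calls: dict[tuple[str, int], VariantCall] = {}
    for counts in pileup:
        key = (counts.sample_id, counts.np)
        if key in calls:
            raise ValueError(f"duplicate pileup entry for sample {key[0]} np {key[1]}")
        calls[key] = call_position(counts, cfg)

    nps_by_sample: dict[str, set[int]] = defaultdict(set)
    for (sid, np_), call in calls.items():
        if call.reported:
            nps_by_sample[sid].add(np_)

    sites: list[ClassifiedSite] = []
    comparisons: list[SiteComparison] = []
    skipped: list[tuple[str, int, str]] = []
    for quartet in quartets:
        candidate_nps: set[int] = set()
        for slot in SLOTS:
            sid = quartet.sample(slot)
            if sid:
                candidate_nps |= nps_by_sample.get(sid, set())
        for np_ in sorted(candidate_nps):
            slot_calls = {}
            missing = None
            for slot in SLOTS:
                sid = quartet.sample(slot)
                if sid is None or (sid, np_) not in calls:
                    missing = slot
                    break
                slot_calls[slot] = calls[(sid, np_)]
            if missing is not None:
                logger.warning(
                    "family %s np %d: no data for slot %s; site skipped",
                    quartet.family_id, np_, missing,
                )
                skipped.append((quartet.family_id, np_, missing))
                continue
            site = classify_site(quartet.family_id, np_, slot_calls, cfg)
            if site is None:
                continue
            if reference is not None:
                site = _annotate(site, slot_calls, reference)
            sites.append(site)
            if site.label == DIFFERENTIATING:
                comparisons.append(site_comparison(site))
    return ClassificationResult(sites, comparisons, len(quartets), skipped)


def _annotate(
    site: ClassifiedSite,
    slot_calls: Mapping[str, VariantCall],
    reference: MtReference,
) -> ClassifiedSite:
    ref_base = reference.base(site.np)
    alt = None
    for slot in site.reported_slots():
        call = slot_calls[slot]
        for allele in (call.minor_allele, call.major_allele):
            if allele and allele != ref_base:
                alt = allele
                break
        if alt:
            break
    if alt is None:
        logger.warning(
            "family %s np %d: no non-reference allele found; effect not annotated",
            site.family_id, site.np,
        )
        return site
    try:
        effect = reference.substitution_effect(site.np, ref_base, alt)
    except ValueError as exc:
        logger.warning("annotation failed at np %d: %s", site.np, exc)
        return site
    return ClassifiedSite(
        site.family_id, site.np, site.label, site.carrier, site.minor_pct,
        site.primary_haplotype_change, effect,
    )
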
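"""Packaged transcriptions of the published summary tables, and pileup
reconstruction of the full 39-family cohort from them.

Two tables drive the desk-scale fixtures:

* the *differentiating* table prints full read counts (forward:reverse for
  major and minor alleles) for 21 sites across 17 families — pileups are
  rebuilt from those counts exactly, with the total coverage inferred from
  the printed major percentage (the printed denominators include third and
  fourth alleles) and the residual reads assigned to the remaining bases;
* the *shared* table prints only minor-variant percentages for 14 sites in
  12 families — pileups are synthesized at fixed coverage 10,000 reproducing
  each percentage to two decimals, with non-detected slots emitted flat.

Seven families appear in both tables and are merged by their sample codes;
the remaining 17 families of the 39-pair cohort are emitted flat (no minor
alleles) at coverage 10,000 at every fixture position.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .calling import BASES, AlleleCounts
from .reference import MtReference

#: sha256 of the packaged transcriptions; load fails hard on mismatch
_CHECKSUMS = {
    "table1_shared.tsv": "8d3159ccba2f13e46181c3334482e2ff603cf7f7bb59227d50522ceac701b002",
    "table2_differentiating.tsv": "4132de2064e5f278993e4b98544bfcb180c8e401a837e129b95c650c93a28853",
    "table4_error_hotspots.tsv": "b58b84703cb8bd51e2e8b60b1c32ebb9082003ffb53909e733316e012220d8b1",
}

#: family identity = mother-blood sample code
TABLE1_FAMILY = {1: "M490", 2: "M249", 3: "M234", 4: "M210", 5: "M213", 6: "M512",
                 7: "M520", 8: "SC16", 9: "M494", 10: "M236", 11: "M-188", 12: "M252"}
TABLE2_FAMILY = {1: "M207", 2: "M137", 3: "M502G", 4: "M242", 5: "M132", 6: "M203",
                 7: "M213", 8: "M520", 9: "M500", 10: "SC16", 11: "M494", 12: "M211",
                 13: "M200", 14: "M240", 15: "M236", 16: "M-188", 17: "M252"}
N_COHORT_FAMILIES = 39
FIXTURE_COVERAGE = 10_000

SLOTS = ("mother_buccal", "mother_blood", "child_buccal", "child_blood")


class FixtureIntegrityError(RuntimeError):
    """A packaged table transcription failed its checksum."""


def _read_packaged(name: str) -> pd.DataFrame:
    raw = (resources.files("mthet") / "data" / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _CHECKSUMS.get(name)
    if expected is not None and digest != expected:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != expected {expected}; "
            "the packaged transcription has been altered"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype={"sample_code": str})


def table1() -> pd.DataFrame:
    """Shared-heteroplasmy table: one row per (pair, slot, np)."""
    df = _read_packaged("table1_shared.tsv")
    df["family_id"] = df["pair"].map(TABLE1_FAMILY)
    return df


def table2() -> pd.DataFrame:
    """Differentiating-heteroplasmy table: one row per (pair, np, slot)."""
    df = _read_packaged("table2_differentiating.tsv")
    df["family_id"] = df["pair"].map(TABLE2_FAMILY)
    return df


def table4() -> pd.DataFrame:
    """Error-hotspot table: adjacent sequence, reference base, np, error %."""
    return _read_packaged("table4_error_hotspots.tsv")


def _split_strands(n: int) -> tuple[int, int]:
    return n - n // 2, n // 2


def _counts_from_table2_row(row) -> AlleleCounts:
    major, minor = row["major"], row["minor"]
    maj_n = int(row["major_fwd"]) + int(row["major_rev"])
    min_n = int(row["minor_fwd"]) + int(row["minor_rev"])
    total = round(maj_n / (float(row["major_pct"]) / 100.0))
    residual = max(total - maj_n - min_n, 0)
    others = [b for b in BASES if b not in (major, minor)]
    o1, o2 = residual - residual // 2, residual // 2
    fwd = {b: 0 for b in BASES}
    rev = {b: 0 for b in BASES}
    fwd[major], rev[major] = int(row["major_fwd"]), int(row["major_rev"])
    fwd[minor], rev[minor] = int(row["minor_fwd"]), int(row["minor_rev"])
    fwd[others[0]], rev[others[0]] = _split_strands(o1)
    fwd[others[1]], rev[others[1]] = _split_strands(o2)
    return AlleleCounts(str(row["sample_code"]), int(row["np"]), fwd, rev)


def _counts_synth(sample_id: str, np_: int, major: str, minor: str | None,
                  pct: float | None, coverage: int = FIXTURE_COVERAGE) -> AlleleCounts:
    fwd = {b: 0 for b in BASES}
    rev = {b: 0 for b in BASES}
    n_minor = 0 if pct is None else round(pct / 100.0 * coverage)
    if minor is not None and n_minor > 0 and minor != major:
        fwd[minor], rev[minor] = _split_strands(n_minor)
    else:
        n_minor = 0
    f, r = _split_strands(coverage - n_minor)
    fwd[major] += f
    rev[major] += r
    return AlleleCounts(sample_id, np_, fwd, rev)


@dataclass
class FixtureCohort:
    """Reconstructed 39-family cohort: pileup rows plus the sample manifest."""

    pileup: list[AlleleCounts]
    manifest: list[dict]
    nps: tuple[int, ...]
    table1_nps: tuple[int, ...]
    table2_nps: tuple[int, ...]

    def family_of_table1_pair(self, pair: int) -> str:
        return TABLE1_FAMILY[pair]

    def family_of_table2_pair(self, pair: int) -> str:
        return TABLE2_FAMILY[pair]


def fixtures_from_tables(reference: MtReference | None = None) -> FixtureCohort:
    """Build the full fixture cohort from the packaged table transcriptions."""
    reference = reference or MtReference.load()
    t1, t2 = table1(), table2()
    t1_nps = tuple(sorted(t1["np"].unique()))
    t2_nps = tuple(sorted(t2["np"].unique()))
    all_nps = tuple(sorted(set(t1_nps) | set(t2_nps)))

    # sample codes per (family, slot), merged across the two tables
    codes: dict[tuple[str, str], str] = {}
    for df in (t1, t2):
        for _, row in df.iterrows():
            key = (row["family_id"], row["slot"])
            code = str(row["sample_code"])
            prev = codes.get(key)
            if prev is not None and prev != code:
                raise FixtureIntegrityError(
                    f"sample code clash for {key}: {prev} vs {code}"
                )
            codes[key] = code
    listed_families = sorted({f for f, _ in codes})
    flat_families = [f"U{i:02d}" for i in range(1, N_COHORT_FAMILIES - len(listed_families) + 1)]
    for fam in flat_families:
        for slot in SLOTS:
            short = {"mother_buccal": "MBu", "mother_blood": "MBl",
                     "child_buccal": "CBu", "child_blood": "CBl"}[slot]
            codes[(fam, slot)] = f"{fam}-{short}"

    manifest = []
    for (fam, slot), code in sorted(codes.items()):
        role, tissue = slot.split("_")
        manifest.append(
            {"sample_id": code, "family_id": fam, "role": role, "tissue": tissue}
        )

    # printed data lookup: (family, slot, np) -> row
    t2_rows = {(r["family_id"], r["slot"], int(r["np"])): r for _, r in t2.iterrows()}
    t1_rows = {(r["family_id"], r["slot"], int(r["np"])): r for _, r in t1.iterrows()}

    pileup: list[AlleleCounts] = []
    families = listed_families + flat_families
    for fam in families:
        for slot in SLOTS:
            sid = codes[(fam, slot)]
            for np_ in all_nps:
                key = (fam, slot, np_)
                if key in t2_rows:
                    pileup.append(_counts_from_table2_row(t2_rows[key]))
                elif key in t1_rows:
                    row = t1_rows[key]
                    pct = None if row["minor_pct"] == "ND" else float(row["minor_pct"])
                    pileup.append(
                        _counts_synth(sid, np_, row["major"], row["minor"], pct)
                    )
                else:
                    pileup.append(
                        _counts_synth(sid, np_, reference.base(np_), None, None)
                    )
    return FixtureCohort(pileup, manifest, all_nps, t1_nps, t2_nps)
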
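"""Readers and writers for the pipeline's tabular formats.

All tables are plain TSV with documented headers. Count tables use the
columns ``transcript_id, position, sample_id, a_count, c_count, g_count,
t_count``; site tables use ``transcript_id, position, ref_base
[, in_vivo_level]``. A converter from samtools text pileup to filtered
base counts is included so per-site counts can be produced directly from
``samtools mpileup`` output.
"""

from __future__ import annotations

import os
from collections.abc import Iterable
from typing import TextIO

import pandas as pd

from axonedit.model import EditingSite, QualityFilterConfig

COUNT_COLUMNS = [
    "transcript_id",
    "position",
    "sample_id",
    "a_count",
    "c_count",
    "g_count",
    "t_count",
]

SITE_COLUMNS = ["transcript_id", "position", "ref_base", "in_vivo_level"]


class ParseError(ValueError):
    """Raised on malformed input rows; message names the offending line."""


def read_site_table(path: str | os.PathLike) -> list[EditingSite]:
    """Read a known-editing-site TSV into a list of :class:`EditingSite`.

    Required columns: ``transcript_id``, ``position``, ``ref_base``.
    Optional: ``in_vivo_level`` (fraction in [0,1]). A row whose
    ``ref_base`` is not ``'A'`` or whose (transcript_id, position) repeats
    an earlier row raises :class:`ParseError`.
    """
    sites: list[EditingSite] = []
    seen: set[tuple[str, int]] = set()
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["transcript_id", "position", "ref_base"]
        if header[: len(required)] != required:
            raise ParseError(
                f"{path}: expected header starting with {required}, got {header}"
            )
        has_level = "in_vivo_level" in header
        level_idx = header.index("in_vivo_level") if has_level else -1
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            try:
                position = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {fields[1]!r}") from exc
            level = None
            if has_level and level_idx < len(fields) and fields[level_idx] != "":
                try:
                    level = float(fields[level_idx])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad in_vivo_level {fields[level_idx]!r}"
                    ) from exc
            try:
                site = EditingSite(fields[0], position, fields[2], level)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if site.key in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate site {site.transcript_id}:{site.position}"
                )
            seen.add(site.key)
            sites.append(site)
    return sites


def write_site_table(sites: Iterable[EditingSite], path: str | os.PathLike) -> None:
    rows = [
        {
            "transcript_id": s.transcript_id,
            "position": s.position,
            "ref_base": s.ref_base,
            "in_vivo_level": "" if s.in_vivo_level is None else repr(s.in_vivo_level),
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-sample per-site base-count TSV.

    Returns a DataFrame with :data:`COUNT_COLUMNS`. Counts must be
    non-negative integers; duplicate (transcript_id, position, sample_id)
    rows raise :class:`ParseError`.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "transcript_id": str,
                "sample_id": str,
            },
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[COUNT_COLUMNS]
    for col in ("position", "a_count", "c_count", "g_count", "t_count"):
        values = df[col]
        as_int = pd.to_numeric(values, errors="coerce")
        if as_int.isna().any() or (as_int != as_int.round()).any():
            bad = df.index[as_int.isna() | (as_int != as_int.round())][0]
            raise ParseError(
                f"{path}: row {bad + 2}: non-integer value in column {col!r}"
            )
        df[col] = as_int.astype(int)
    count_cols = ["a_count", "c_count", "g_count", "t_count"]
    if (df[count_cols] < 0).any().any():
        raise ParseError(f"{path}: negative count")
    dup = df.duplicated(subset=["transcript_id", "position", "sample_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate row for {r.transcript_id}:{r.position} "
            f"sample {r.sample_id}"
        )
    return df


def write_count_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_results_table(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any result DataFrame as TSV at full float precision.

    Floats are serialized with ``repr`` round-trip precision so a
    write/read cycle reproduces values bit-identically.
    """
    if results is None:
        raise ValueError("results must not be None")
    results.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# samtools text-pileup conversion
# ---------------------------------------------------------------------------

_BASE_CALLS = set("ACGTNacgtn")


def _parse_pileup_bases(bases: str, quals: str, ref: str, where: str) -> list[tuple[str, int]]:
    """Expand one pileup base string into (base, phred) call tuples.

    Handles the standard dialect: ``^X`` read start (X encodes mapping
    quality), ``$`` read end, ``+N<seq>``/``-N<seq>`` indels, ``*``/``#``
    deletion placeholders and ``<``/``>`` reference skips (these consume a
    quality but are not base calls), ``.``/``,`` reference matches.
    """
    ref = ref.upper()
    calls: list[tuple[str, int]] = []
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret plus mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            length = int(bases[i + 1 : j])
            i = j + length
            continue
        if c in "*#<>":
            if qi >= len(quals):
                raise ParseError(f"{where}: base/quality length mismatch")
            qi += 1
            i += 1
            continue
        if c in ".,":
            base = ref
        elif c in _BASE_CALLS:
            base = c.upper()
        else:
            raise ParseError(f"{where}: unexpected pileup character {c!r}")
        if qi >= len(quals):
            raise ParseError(f"{where}: base/quality length mismatch")
        calls.append((base, ord(quals[qi]) - 33))
        qi += 1
        i += 1
    if qi != len(quals):
        raise ParseError(f"{where}: base/quality length mismatch")
    return calls


def counts_from_pileup(
    pileup_lines: Iterable[str] | TextIO,
    sites: Iterable[EditingSite],
    qc: QualityFilterConfig | None = None,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Convert samtools text pileup to filtered base counts at known sites.

    Only positions present in ``sites`` are counted; base calls with Phred
    quality below ``qc.min_base_quality`` are dropped. Mapping quality
    cannot be re-checked at the pileup stage and is assumed enforced
    upstream. Listed sites absent from the pileup are emitted with zero
    counts.
    """
    qc = qc or QualityFilterConfig()
    wanted = {s.key: s for s in sites}
    counts: dict[tuple[str, int], dict[str, int]] = {
        key: {"A": 0, "C": 0, "G": 0, "T": 0} for key in wanted
    }
    for lineno, line in enumerate(pileup_lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"pileup line {lineno}: expected >=6 columns")
        chrom, pos_s, ref, _depth, bases, quals = fields[:6]
        key = (chrom, int(pos_s))
        if key not in wanted:
            continue
        for base, q in _parse_pileup_bases(bases, quals, ref, f"pileup line {lineno}"):
            if q >= qc.min_base_quality and base in "ACGT":
                counts[key][base] += 1
    rows = [
        {
            "transcript_id": tid,
            "position": pos,
            "sample_id": sample_id,
            "a_count": c["A"],
            "c_count": c["C"],
            "g_count": c["G"],
            "t_count": c["T"],
        }
        for (tid, pos), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return df.sort_values(["transcript_id", "position"]).reset_index(drop=True)


def read_design_table(path: str | os.PathLike):
    """Read a design TSV (columns: sample_id, compartment [, pair_id]).

    Compartment values must form exactly two groups; the lexicographically
    first group label becomes compartment A unless labels are 'GA'/'GFL',
    in which case GA is A. Returns a :class:`CompartmentDesign`.
    """
    from axonedit.model import CompartmentDesign

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "compartment"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    groups = sorted(df["compartment"].unique())
    if len(groups) != 2:
        raise ParseError(f"{path}: expected exactly 2 compartments, got {groups}")
    if set(groups) == {"GA", "GFL"}:
        a_label, b_label = "GA", "GFL"
    else:
        a_label, b_label = groups
    a = tuple(df.loc[df["compartment"] == a_label, "sample_id"])
    b = tuple(df.loc[df["compartment"] == b_label, "sample_id"])
    pairing = None
    if "pair_id" in df.columns and df["pair_id"].notna().all():
        by_pair = df.groupby("pair_id")
        pairing = {}
        for _, grp in by_pair:
            if len(grp) != 2 or set(grp["compartment"]) != {a_label, b_label}:
                raise ParseError(f"{path}: each pair_id needs one sample per compartment")
            sa = grp.loc[grp["compartment"] == a_label, "sample_id"].iloc[0]
            sb = grp.loc[grp["compartment"] == b_label, "sample_id"].iloc[0]
            pairing[sa] = sb
    return CompartmentDesign(a, b, pairing)


def write_design_table(design, path: str | os.PathLike) -> None:
    rows = []
    pairing = design.pairing or {}
    inv = {v: k for k, v in pairing.items()}
    for s in design.compartment_a_samples:
        rows.append({"sample_id": s, "compartment": "GA", "pair_id": s if pairing else ""})
    for s in design.compartment_b_samples:
        rows.append(
            {"sample_id": s, "compartment": "GFL", "pair_id": inv.get(s, "") if pairing else ""}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
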
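"""Readers and writers for dosage files and the per-marker metrics table.

Supported inputs are the Oxford/IMPUTE2 text formats: a GEN dosage file
(one marker per line — five identity columns followed by 3N genotype
probabilities, optionally gzip-compressed) with its companion SAMPLE file,
plus an optional VCF route through the per-genotype probability (GP)
FORMAT field.  Markers stream one record at a time; the whole file is
never materialized.

Triplet hygiene: probability triplets whose sum deviates from 1 by at most
1e-3 (common with rounded GEN output) are renormalized; larger deviations
raise in ``strict`` mode or blank the individual (treated as missing) in
``lenient`` mode.  An all-zero triplet is IMPUTE2's missing-genotype
convention and is preserved as-is; downstream metrics exclude it.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DosageValidationError",
    "MarkerRecord",
    "SampleSet",
    "read_sample_file",
    "iter_gen_markers",
    "iter_vcf_markers",
    "write_gen",
    "write_sample_file",
    "compute_metrics",
    "write_metrics_table",
    "read_metrics_table",
    "METRICS_COLUMNS",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DosageValidationError(ValueError):
    """A probability triplet violates the normalization contract."""


_SUM_TOL = 1e-3          # renormalize within this; reject/skip beyond it
_EXACT_TOL = 1e-9        # below this the triplet is left untouched
_CHROM_RE = re.compile(r"^(chr)?([0-9]{1,2}|X|Y|XY|MT?)$", re.IGNORECASE)
_CHROM_FNAME_RE = re.compile(r"chr[._-]?([0-9]{1,2}|X|Y|MT?)", re.IGNORECASE)


@dataclass
class MarkerRecord:
    """One marker's identity plus its N x 3 dosage matrix.

    ``n_renormalized`` counts triplets rescaled to sum 1;
    ``n_skipped`` counts triplets blanked under lenient parsing.
    """

    snp_id: str
    rs_id: str
    chrom: str | None
    position: int
    allele_a: str
    allele_b: str
    probs: np.ndarray
    n_renormalized: int = 0
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class SampleSet:
    """Ordered individual identifiers from an Oxford SAMPLE file."""

    sample_ids: tuple = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _open_text(path):
    path = str(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sample_file(path) -> SampleSet:
    """Parse an Oxford SAMPLE file: two header lines, one line per individual.

    The first token of each data line is taken as the sample identifier.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(
            f"{path}: SAMPLE file needs 2 header lines, found {len(lines)} line(s)"
        )
    header = lines[0].split()
    if len(header) < 1:
        raise FormatError(f"{path}: malformed SAMPLE header at line 1")
    ids = tuple(ln.split()[0] for ln in lines[2:])
    return SampleSet(sample_ids=ids)


def is_chrom_label(token: str) -> bool:
    """True when a token looks like a chromosome label (1-22, X, Y, MT)."""
    m = _CHROM_RE.match(token)
    if not m:
        return False
    body = m.group(2)
    if body.isdigit():
        return 1 <= int(body) <= 26
    return True


def _chrom_from_filename(path) -> str | None:
    m = _CHROM_FNAME_RE.search(str(path))
    return m.group(1) if m else None


def _parse_probs(raw, snp_id, lineno, policy):
    """Validate and normalize a flat probability vector; returns (probs, n_renorm, n_skip)."""
    probs = raw.reshape(-1, 3)
    if np.any(probs < 0.0) or np.any(probs > 1.0 + _SUM_TOL):
        bad = int(np.where((probs < 0.0) | (probs > 1.0 + _SUM_TOL))[0][0])
        raise DosageValidationError(
            f"line {lineno} ({snp_id}): probability outside [0, 1] for individual {bad + 1}"
        )
    sums = probs.sum(axis=1)
    missing = sums == 0.0
    off = ~missing & (np.abs(sums - 1.0) > _EXACT_TOL)
    bad = ~missing & (np.abs(sums - 1.0) > _SUM_TOL)
    n_skipped = 0
    if bad.any():
        if policy == "strict":
            idx = int(np.where(bad)[0][0])
            raise DosageValidationError(
                f"line {lineno} ({snp_id}): triplet sum {sums[bad][0]:.6f} outside "
                f"[{1 - _SUM_TOL}, {1 + _SUM_TOL}] for individual {idx + 1}"
            )
        probs[bad] = 0.0  # lenient: treat as missing
        n_skipped = int(bad.sum())
        off &= ~bad
    if off.any():
        probs[off] /= sums[off, None]
    return probs, int(off.sum()), n_skipped


def iter_gen_markers(path, expected_n=None, chrom=None, policy="strict"):
    """Stream :class:`MarkerRecord` objects from a GEN dosage file.

    The usual dialect carries 5 identity columns (snp id, rs id, position,
    allele A, allele B); a 6-column dialect with the chromosome first is
    auto-detected when the first token is a valid chromosome label and the
    remaining column count fits 3 probabilities per individual.  The
    chromosome label otherwise comes from the ``chrom`` argument or, as a
    fallback, a ``chrN`` pattern in the file name.  Gzip input is detected
    from the file's magic bytes.

    ``policy`` is ``"strict"`` (raise on badly normalized triplets) or
    ``"lenient"`` (blank them and count them in ``n_skipped``).
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    file_chrom = chrom if chrom is not None else _chrom_from_filename(path)
    six_col = None  # decided on the first line
    n_expected = expected_n
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if six_col is None:
                six_col = (
                    chrom is None
                    and len(tokens) > 6
                    and is_chrom_label(tokens[0])
                    and (len(tokens) - 6) % 3 == 0
                    and (len(tokens) - 5) % 3 != 0
                )
            lead = 6 if six_col else 5
            if len(tokens) <= lead or (len(tokens) - lead) % 3 != 0:
                raise FormatError(
                    f"{path}: line {lineno}: {len(tokens)} columns do not fit "
                    f"{lead} identity columns + 3 probabilities per individual"
                )
            if six_col:
                line_chrom, snp_id, rs_id, pos_s, a, b = tokens[:6]
            else:
                line_chrom = file_chrom
                snp_id, rs_id, pos_s, a, b = tokens[:5]
            try:
                position = int(pos_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            if position < 1:
                raise FormatError(f"{path}: line {lineno}: position {position} < 1")
            try:
                raw = np.array(tokens[lead:], dtype=float)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric probability"
                ) from None
            n_ind = raw.size // 3
            if n_expected is None:
                n_expected = n_ind
            if n_ind != n_expected:
                raise FormatError(
                    f"{path}: line {lineno}: {n_ind} individuals, expected {n_expected}"
                )
            probs, n_renorm, n_skip = _parse_probs(raw, snp_id, lineno, policy)
            yield MarkerRecord(
                snp_id=snp_id,
                rs_id=rs_id,
                chrom=str(line_chrom) if line_chrom is not None else None,
                position=position,
                allele_a=a,
                allele_b=b,
                probs=probs,
                n_renormalized=n_renorm,
                n_skipped=n_skip,
            )


def iter_vcf_markers(path, field="GP", policy="strict"):
    """Stream markers from a VCF carrying per-genotype probabilities.

    The FORMAT ``field`` (default ``GP``) must hold the (hom-ref, het,
    hom-alt) probability triplet; it is mapped to ``(p0, p1, p2)`` with the
    allele dose counting the ALT allele.  Missing per-sample values become
    all-zero (missing) triplets.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    for lineno, var in enumerate(vcf, start=1):
        arr = var.format(field)
        if arr is None:
            raise FormatError(
                f"{path}: record {lineno} ({var.ID or var.POS}): no {field} field"
            )
        raw = np.asarray(arr, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != 3:
            raise FormatError(
                f"{path}: record {lineno}: {field} is not a genotype-probability triplet"
            )
        raw = np.where(np.isfinite(raw), raw, 0.0)
        sums = raw.sum(axis=1)
        raw[sums == 0.0] = 0.0
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        probs, n_renorm, n_skip = _parse_probs(raw.ravel(), snp_id, lineno, policy)
        yield MarkerRecord(
            snp_id=snp_id,
            rs_id=snp_id,
            chrom=str(var.CHROM),
            position=int(var.POS),
            allele_a=var.REF,
            allele_b=var.ALT[0] if var.ALT else ".",
            probs=probs,
        )


def write_sample_file(sample_ids, path):
    """Write a minimal Oxford SAMPLE file for the given identifiers."""
    with open(path, "wt") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0\n")


def write_gen(records, path):
    """Write marker records as a 5-column GEN file (gzip if path ends .gz).

    Probabilities are written with shortest round-tripping decimal
    representation, so reading the file back reproduces them bit-exactly.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            head = f"{rec.snp_id} {rec.rs_id} {rec.position} {rec.allele_a} {rec.allele_b}"
            body = " ".join(repr(float(x)) for x in rec.probs.ravel())
            fh.write(f"{head} {body}\n")


METRICS_COLUMNS = [
    "snp_id",
    "rs_id",
    "chrom",
    "position",
    "maf_hat",
    "q_bar",
    "iam_chance",
    "iam_hwe",
    "hiq",
    "n_used",
    "flags",
]

_FLOAT_COLS = ["maf_hat", "q_bar", "iam_chance", "iam_hwe", "hiq"]


def compute_metrics(records, founder_mask=None) -> pd.DataFrame:
    """Run the per-marker accuracy computation over a record stream.

    Returns one metrics row per input marker (none dropped), sorted by
    (chrom, position).  ``founder_mask`` restricts the allele-frequency
    estimate as in :func:`iamhiq.metrics.compute_marker`.
    """
    from . import metrics as _metrics

    rows = []
    for rec in records:
        acc = _metrics.compute_marker(rec, founder_mask=founder_mask)
        rows.append(
            {
                "snp_id": rec.snp_id,
                "rs_id": rec.rs_id,
                "chrom": rec.chrom if rec.chrom is not None else ".",
                "position": rec.position,
                "maf_hat": acc.maf_hat,
                "q_bar": acc.q_bar,
                "iam_chance": acc.iam_chance,
                "iam_hwe": acc.iam_hwe,
                "hiq": acc.hiq,
                "n_used": acc.n_used,
                "flags": acc.flags,
            }
        )
    table = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    if len(table):
        table = table.sort_values(
            ["chrom", "position"], kind="stable", ignore_index=True
        )
    return table


def write_metrics_table(table: pd.DataFrame, path) -> None:
    """Write the per-marker metrics table as TSV (floats at 6 sig. digits)."""
    missing = [c for c in METRICS_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"metrics table lacks columns: {missing}")
    out = table.loc[:, METRICS_COLUMNS].copy()
    out["flags"] = out["flags"].map(_format_flags)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _format_flags(flags) -> str:
    if isinstance(flags, str):
        return flags if flags else "."
    if not flags:
        return "."
    return ",".join(sorted(flags))


def _parse_flags(s) -> frozenset:
    if not isinstance(s, str) or s in (".", ""):
        return frozenset()
    return frozenset(s.split(","))


def read_metrics_table(path) -> pd.DataFrame:
    """Read a metrics TSV written by :func:`write_metrics_table`."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in METRICS_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: metrics table lacks columns: {missing}")
    table["flags"] = table["flags"].map(_parse_flags)
    table["position"] = table["position"].astype(int)
    table["n_used"] = table["n_used"].astype(int)
    return table
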
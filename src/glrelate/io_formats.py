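"""File formats: beagle genotype-likelihood tables, VCF/BCF, frequency
files, pedigree trio files and per-pair result tables.

Genotype likelihoods are normalized to per-site maximum 1 immediately on
read (likelihood scale is arbitrary), so downstream code never sees raw
phred/log10 encodings.  Site identifiers are carried as ``chrom_pos``
strings; VCF positions stay 1-based as in the standard.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import normalize_gl
from .summaries import RESULT_COLUMNS

__all__ = [
    "GlDataset",
    "ParseError",
    "read_beagle_gl",
    "write_beagle_gl",
    "read_vcf_gls",
    "read_frequencies",
    "write_frequencies",
    "filter_sites",
    "write_results",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class GlDataset:
    """Per-individual genotype likelihoods plus site metadata.

    ``gls[k]`` is the (L, 3) linear-scale, max-normalized likelihood table
    of individual ``sample_ids[k]``; ``site_ids`` has length L.  ``freqs``
    is filled only when frequencies travel with the source (VCF AF tag).
    """

    sample_ids: list[str]
    site_ids: list[str]
    gls: list[np.ndarray]
    freqs: np.ndarray | None = None
    n_skipped: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _opener(path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)


def read_beagle_gl(path, scale: str = "auto") -> GlDataset:
    """Read a beagle-style genotype-likelihood text table.

    Layout: a header line, then one row per site with marker id, the two
    allele codes, and three likelihood columns per individual (genotypes
    0, 1, 2 copies of the second-listed allele).  Gzip-compressed files
    are accepted.  ``scale`` is ``"linear"``, ``"log10"`` or ``"auto"``
    (negative values present => log10).
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap any pandas failure
        raise ParseError(f"{path}: cannot parse beagle table: {exc}") from exc
    if df.shape[1] < 6 or (df.shape[1] - 3) % 3 != 0:
        raise ParseError(
            f"{path}: expected 3 leading columns plus 3 per individual; "
            f"got {df.shape[1]} columns"
        )
    site_ids = df.iloc[:, 0].tolist()
    values = df.iloc[:, 3:]
    bad = values.isna().any(axis=1)
    if bad.any():
        raise ParseError(f"{path}: ragged or missing entries on data line {int(np.argmax(bad.values)) + 2}")
    try:
        raw = values.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric likelihood entry: {exc}") from exc
    if scale == "auto":
        scale = "log10" if (raw < 0).any() else "linear"
    if scale == "log10":
        raw = 10.0**raw
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    if (raw < 0).any():
        raise ParseError(f"{path}: negative linear-scale likelihoods")
    n_samples = raw.shape[1] // 3
    gls = []
    for k in range(n_samples):
        tab = raw[:, 3 * k : 3 * k + 3]
        # all-zero rows carry no information: treat as missing => flat
        empty = tab.max(axis=1) == 0
        tab = normalize_gl(tab)
        tab[empty] = 1.0
        gls.append(tab)
    header = df.columns.tolist()
    names = [header[3 + 3 * k] for k in range(n_samples)]
    # beagle headers repeat the individual name thrice; fall back to Ind{k}
    if len(set(names)) != n_samples:
        names = [f"Ind{k}" for k in range(n_samples)]
    return GlDataset(sample_ids=names, site_ids=site_ids, gls=gls)


def write_beagle_gl(path, dataset: GlDataset, alleles: tuple[str, str] = ("0", "1")) -> None:
    """Write a beagle GL table (inverse of :func:`read_beagle_gl`)."""
    with (gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")) as fh:
        cols = ["marker", "allele1", "allele2"]
        for name in dataset.sample_ids:
            cols += [name] * 3
        fh.write("\t".join(cols) + "\n")
        stacked = np.hstack(dataset.gls)
        for l, site in enumerate(dataset.site_ids):
            row = "\t".join(f"{v:.6g}" for v in stacked[l])
            fh.write(f"{site}\t{alleles[0]}\t{alleles[1]}\t{row}\n")


def read_vcf_gls(path, tag: str = "PL", af_from_info: bool = False) -> GlDataset:
    """Read genotype likelihoods from a VCF/BCF.

    Only biallelic SNV records are used; others are skipped and counted.
    ``tag`` selects the FORMAT field: ``"PL"`` (phred, ``10^(-x/10)``) or
    ``"GL"`` (log10, ``10^x``).  Missing per-sample values become flat
    rows.  With ``af_from_info`` the INFO/AF tag is collected as the
    alternate-allele frequency for each retained site.
    """
    from cyvcf2 import VCF

    if tag not in ("PL", "GL"):
        raise ValueError(f"tag must be 'PL' or 'GL'; got {tag!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    site_ids: list[str] = []
    freqs: list[float] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_skipped += 1
            continue
        try:
            field = variant.format(tag)
        except KeyError:
            field = None
        if field is None:
            n_skipped += 1
            continue
        field = np.asarray(field, dtype=float)[:, :3]
        if tag == "PL":
            missing = ~np.isfinite(field) | (field < 0)
            linear = 10.0 ** (-field / 10.0)
        else:
            missing = ~np.isfinite(field)
            linear = 10.0**field
        linear[missing.any(axis=1)] = 1.0
        rows.append(linear)
        site_ids.append(f"{variant.CHROM}_{variant.POS}")
        if af_from_info:
            af = variant.INFO.get("AF")
            freqs.append(float(af[0] if isinstance(af, tuple) else af) if af is not None else math.nan)
    vcf.close()
    if not rows:
        raise ParseError(f"{path}: no usable biallelic SNV records with {tag} found")
    cube = np.stack(rows)  # (L, N, 3)
    gls = [normalize_gl(cube[:, k, :]) for k in range(len(samples))]
    return GlDataset(
        sample_ids=samples, site_ids=site_ids, gls=gls,
        freqs=np.asarray(freqs) if af_from_info else None,
        n_skipped=n_skipped,
    )


def read_frequencies(path) -> np.ndarray:
    """Read a plain-text frequency file: one frequency per line, in site order."""
    values: list[float] = []
    with _opener(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: non-numeric frequency {s!r}") from exc
    return np.asarray(values, dtype=float)


def write_frequencies(path, freqs: np.ndarray) -> None:
    with open(path, "w") as fh:
        for f in np.asarray(freqs, dtype=float):
            fh.write(f"{f:.8g}\n")


def filter_sites(
    gls: list[np.ndarray],
    freqs: np.ndarray,
) -> tuple[list[np.ndarray], np.ndarray, int]:
    """Drop sites whose frequency falls outside (0, 1).

    The estimator's emission model is undefined at fixed sites; they carry
    no relatedness information anyway.  Returns the filtered tables, the
    filtered frequencies and the number of sites removed.  Raises if the
    frequency vector length does not match the GL tables.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_sites = gls[0].shape[0]
    if freqs.shape[0] != n_sites:
        raise ValueError(
            f"frequency file has {freqs.shape[0]} sites but GL input has {n_sites}"
        )
    keep = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    n_dropped = int((~keep).sum())
    if n_dropped == 0:
        return gls, freqs, 0
    return [g[keep] for g in gls], freqs[keep], n_dropped


def _format_value(col: str, value) -> str:
    if col in ("ida", "idb"):
        return str(value)
    if col in ("nSites", "nIter", "seed", "converged"):
        return str(int(value))
    v = float(value)
    return "nan" if math.isnan(v) else f"{v:.6g}"


def write_results(path, rows: list[dict]) -> None:
    """Write the per-pair results table (tab-separated, fixed column order).

    Every row must provide all columns of the public contract
    (:data:`glrelate.summaries.RESULT_COLUMNS`); floats are printed at 6
    significant digits, so identical inputs give byte-identical files.
    """
    if not rows:
        raise ValueError("no result rows to write")
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            missing = [c for c in RESULT_COLUMNS if c not in row]
            if missing:
                raise ValueError(f"result row missing columns: {missing}")
            fh.write("\t".join(_format_value(c, row[c]) for c in RESULT_COLUMNS) + "\n")
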
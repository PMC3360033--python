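"""Packaged study fixtures and TSV I/O for profile tables.

The package ships the study's two printed data tables as TSV fixtures:
23 taxon composition profiles (8 subjects, storage conditions C1-C3, one
subject missing C2) and 24 metabolite records quantified from 1D proton
NMR. Taxon percentages cover only the top 20 taxa, so each profile gets
an explicit "Other" remainder taxon to close the composition.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .types import MetaboliteRecord, NMRSpectrum, TaxonProfile

_META_COLS = ["sample_id", "subject_id", "condition", "cst", "total_reads"]


def _fixture_path(name: str):
    return resources.files("microstab.data").joinpath(name)


def _profiles_from_frame(df: pd.DataFrame) -> list[TaxonProfile]:
    taxa = [c for c in df.columns if c not in _META_COLS]
    profiles = []
    for _, row in df.iterrows():
        props = {t: float(row[t]) / 100.0 for t in taxa}
        rem = 1.0 - sum(props.values())
        if rem < 0:
            if rem < -1e-9:
                warnings.warn(
                    f"sample {row['sample_id']}: taxa sum to {100 * (1 - rem):.2f}% "
                    "(> 100, rounding); clipping 'Other' remainder to 0"
                )
            rem = 0.0
        props["Other"] = rem
        cst = row.get("cst")
        profiles.append(
            TaxonProfile(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                condition=str(row["condition"]),
                total_reads=int(row["total_reads"]),
                proportions=props,
                cst=None if pd.isna(cst) or cst == "NA" else str(cst),
            )
        )
    return profiles


def load_table2() -> list[TaxonProfile]:
    """Load the packaged 23-sample taxon composition fixture.

    Returns one :class:`TaxonProfile` per sample with percentages rescaled
    to fractions and the "Other" remainder appended so each vector sums
    to 1.
    """
    try:
        with _fixture_path("table2_profiles.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise RuntimeError("taxon profile fixture missing or corrupt") from exc
    return _profiles_from_frame(df)


def load_table3() -> list[MetaboliteRecord]:
    """Load the packaged 24-sample NMR metabolite fixture.

    The one sample without a community state type (its 16S amplicon
    failed) has ``cst=None``.
    """
    try:
        with _fixture_path("table3_metabolites.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=["NA"])
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise RuntimeError("metabolite fixture missing or corrupt") from exc
    records = []
    for _, row in df.iterrows():
        records.append(
            MetaboliteRecord(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                condition=str(row["condition"]),
                lactic_pct=float(row["lactic_pct"]),
                acetic_pct=float(row["acetic_pct"]),
                succinic_pct=float(row["succinic_pct"]),
                cst=None if pd.isna(row["cst"]) else str(row["cst"]),
            )
        )
    return records


def write_profiles(profiles: Sequence[TaxonProfile], path) -> None:
    """Write profiles in the fixture TSV dialect (percent scale, no 'Other')."""
    taxa: list[str] = []
    seen = set()
    for p in profiles:
        for t in p.proportions:
            if t != "Other" and t not in seen:
                seen.add(t)
                taxa.append(t)
    rows = []
    for p in profiles:
        row = {
            "sample_id": p.sample_id,
            "subject_id": p.subject_id,
            "condition": p.condition,
            "cst": p.cst if p.cst is not None else "NA",
            "total_reads": p.total_reads,
        }
        for t in taxa:
            row[t] = round(100.0 * p.proportions.get(t, 0.0), 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[TaxonProfile]:
    """Read a profile TSV written by :func:`write_profiles`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])
    return _profiles_from_frame(df)


def write_spectrum(spectrum: NMRSpectrum, path) -> None:
    """Two-column (ppm, intensity) TSV with '#' header lines for metadata."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={spectrum.sample_id}\n")
        fh.write(f"# subject_id={spectrum.subject_id}\n")
        fh.write(f"# condition={spectrum.condition}\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.6f}\t{y:.8g}\n")


def read_spectrum(path) -> NMRSpectrum:
    """Read a spectrum TSV written by :func:`write_spectrum`."""
    meta = {"sample_id": "", "subject_id": "", "condition": ""}
    ppm, inten = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key in meta:
                    meta[key] = val
                continue
            a, b = line.split("\t")
            ppm.append(float(a))
            inten.append(float(b))
    return NMRSpectrum(ppm=np.array(ppm), intensity=np.array(inten), **meta)
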
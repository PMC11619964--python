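"""Readers, writers and validated containers for the pipeline's external formats.

Three kinds of tabular input feed the model: a gene-expression matrix, a
per-sample gene-burden matrix derived from annotated variants, and a sample
metadata table carrying the class label, onset age and survival outcome.
Gene sets for enrichment testing arrive as GMT files. Everything is
validated on load so the numerical code never sees duplicate identifiers,
ragged rows or non-finite values.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A malformed input file (duplicate ids, bad values, ragged rows...)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class OmicsBlock:
    """One omics layer: a samples x features matrix of non-negative reals.

    ``name`` identifies the layer ("expression" or "burden"); rows are
    samples, columns are features (genes).
    """

    name: str
    samples: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.features = list(self.features)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.samples, "sample")
        _check_unique(self.features, "feature")
        if self.values.shape != (len(self.samples), len(self.features)):
            raise FormatError(
                f"block {self.name!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.samples)} samples x {len(self.features)} features"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise FormatError(f"block {self.name!r}: non-finite values present")
        if self.values.size and np.any(self.values < 0):
            raise FormatError(f"block {self.name!r}: negative values present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)

    def reindex_samples(self, sample_order: Sequence[str]) -> "OmicsBlock":
        """Return a copy with rows permuted into ``sample_order``."""
        order = list(sample_order)
        if sorted(order) != sorted(self.samples):
            raise FormatError(
                f"block {self.name!r}: requested sample order is not a "
                "permutation of the block's samples"
            )
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in order]
        return OmicsBlock(self.name, order, self.features, self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        """Return a copy restricted to ``sample_ids`` (in the given order)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise FormatError(f"block {self.name!r}: unknown samples {missing[:3]}")
        idx = [pos[s] for s in sample_ids]
        return OmicsBlock(self.name, list(sample_ids), self.features, self.values[idx])

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsBlock":
        """Return a copy restricted to ``feature_ids`` (in the given order)."""
        pos = {f: i for i, f in enumerate(self.features)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise FormatError(f"block {self.name!r}: unknown features {missing[:3]}")
        idx = [pos[f] for f in feature_ids]
        return OmicsBlock(self.name, self.samples, list(feature_ids),
                          self.values[:, idx])


@dataclass
class SampleTable:
    """Per-sample metadata: class label, onset age, survival time and event.

    ``onset_age`` may contain NaN for samples with unknown onset; survival
    time ``T`` is non-negative and the event indicator ``E`` is 0 (censored)
    or 1 (event observed).
    """

    samples: list[str]
    label: np.ndarray          # integer-coded class per sample
    label_names: list[str]     # code -> name
    onset_age: np.ndarray      # float, NaN = missing
    time: np.ndarray           # float, >= 0
    event: np.ndarray          # int, {0, 1}

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        _check_unique(self.samples, "sample")
        n = len(self.samples)
        self.label = np.asarray(self.label, dtype=int)
        self.onset_age = np.asarray(self.onset_age, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        for arr, name in [(self.label, "label"), (self.onset_age, "onset_age"),
                          (self.time, "time"), (self.event, "event")]:
            if arr.shape != (n,):
                raise FormatError(f"column {name}: length {arr.shape} != {n} samples")
        if not np.all(np.isin(self.event, [0, 1])):
            bad = sorted(set(self.event) - {0, 1})
            raise FormatError(f"event indicator outside {{0,1}}: {bad}")
        if np.any(self.time[np.isfinite(self.time)] < 0):
            raise FormatError("negative survival times present")
        if self.label.size and (self.label.min() < 0 or self.label.max() >= len(self.label_names)):
            raise FormatError("label codes outside the declared label set")

    def __len__(self) -> int:
        return len(self.samples)

    def class_counts(self) -> dict[str, int]:
        counts = Counter(self.label_names[c] for c in self.label)
        return dict(counts)

    def reindex_samples(self, sample_order: Sequence[str]) -> "SampleTable":
        order = list(sample_order)
        if sorted(order) != sorted(self.samples):
            raise FormatError("requested sample order is not a permutation")
        return self.subset_samples(order)

    def subset_samples(self, sample_ids: Sequence[str]) -> "SampleTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise FormatError(f"unknown samples {missing[:3]}")
        idx = [pos[s] for s in sample_ids]
        return SampleTable(list(sample_ids), self.label[idx], list(self.label_names),
                           self.onset_age[idx], self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "label": [self.label_names[c] for c in self.label],
                "onset_age": self.onset_age,
                "time": self.time,
                "event": self.event,
            }
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted(k for k, v in Counter(ids).items() if v > 1)
        raise FormatError(f"duplicate {kind} identifiers: {dupes[:5]}")


# ---------------------------------------------------------------------------
# matrix IO


def read_expression_matrix(path: str | Path, orientation: str = "genes_in_rows",
                           name: str = "expression", sep: str = "\t") -> OmicsBlock:
    """Read a delimited expression matrix into a samples x features block.

    ``orientation`` declares the file layout: ``genes_in_rows`` (one row per
    gene, one column per sample; transposed on load) or ``samples_in_rows``.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise FormatError(f"{path}: duplicate row identifiers: {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = sorted(df.columns[df.columns.duplicated()].unique().tolist())
        raise FormatError(f"{path}: duplicate column identifiers: {dupes[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise FormatError(f"{path}: non-numeric cells in columns {list(bad)[:5]}")
    if orientation == "genes_in_rows":
        samples = [str(c) for c in df.columns]
        features = [str(i) for i in df.index]
        values = values.T
    else:
        samples = [str(i) for i in df.index]
        features = [str(c) for c in df.columns]
    try:
        return OmicsBlock(name=name, samples=samples, features=features, values=values)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(block: OmicsBlock, path: str | Path,
                            orientation: str = "genes_in_rows", sep: str = "\t") -> None:
    df = block.to_frame()
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep, index_label="id")


# ---------------------------------------------------------------------------
# sample table IO


def read_sample_table(path: str | Path, sep: str = "\t",
                      sample_col: str = "sample", label_col: str = "label",
                      onset_col: str = "onset_age", time_col: str = "time",
                      event_col: str = "event",
                      label_names: Sequence[str] | None = None) -> SampleTable:
    """Read the sample metadata table with declared column names.

    Missing onset ages are allowed (empty cells become NaN). Event values
    must be 0 or 1.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (sample_col, label_col, onset_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    labels_raw = df[label_col].astype(str).tolist()
    if label_names is None:
        label_names = sorted(set(labels_raw))
    label_names = list(label_names)
    unknown = set(labels_raw) - set(label_names)
    if unknown:
        raise FormatError(f"{path}: labels outside declared set: {sorted(unknown)}")
    code = {name: i for i, name in enumerate(label_names)}
    events = df[event_col]
    if not events.isin([0, 1]).all():
        bad = sorted(set(events) - {0, 1})
        raise FormatError(f"{path}: event values outside {{0,1}}: {bad}")
    try:
        return SampleTable(
            samples=[str(s) for s in df[sample_col]],
            label=np.array([code[l] for l in labels_raw]),
            label_names=label_names,
            onset_age=pd.to_numeric(df[onset_col], errors="raise").to_numpy(dtype=float),
            time=pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float),
            event=events.to_numpy(dtype=int),
        )
    except FormatError:
        raise
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sample_table(table: SampleTable, path: str | Path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GMT IO


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are collapsed (first occurrence kept); a
    set name appearing twice is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: set {name!r} listed twice")
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g, None)
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# annotated variants (VCF with CSQ-style annotation, or flat TSV)

_CSQ_REQUIRED = ("Consequence", "SYMBOL", "CANONICAL")


def read_annotated_variants(path: str | Path, af_field: str = "AF",
                            csq_tag: str = "CSQ"):
    """Read VEP-annotated variants from a VCF into AnnotatedVariant records.

    The VCF must carry a per-ALT annotation INFO field (default ``CSQ``)
    whose header line declares a ``Format:`` with at least Consequence,
    SYMBOL, CANONICAL and the allele-frequency subfield (default ``AF``).
    One record is produced per variant-consequence entry; per-sample
    non-reference allele counts (het=1, hom-alt=2) are attached. An empty
    AF subfield is preserved as absent.
    """
    from cyvcf2 import VCF

    from .variant_prioritization import AnnotatedVariant

    vcf = VCF(str(path))
    fmt = None
    for h in vcf.header_iter():
        info = h.info()
        if info.get("ID") == csq_tag and "Description" in info:
            desc = info["Description"]
            if "Format:" in desc:
                fmt = desc.split("Format:", 1)[1].strip().strip('"').split("|")
    if fmt is None:
        raise FormatError(f"{path}: no {csq_tag} INFO header with a Format declaration")
    missing = [f for f in (*_CSQ_REQUIRED, af_field) if f not in fmt]
    if missing:
        raise FormatError(f"{path}: {csq_tag} Format lacks mandatory subfields: {missing}")
    idx = {f: i for i, f in enumerate(fmt)}
    samples = list(vcf.samples)

    records = []
    for variant in vcf:
        csq = variant.INFO.get(csq_tag)
        if csq is None:
            continue
        counts: dict[str, int] = {}
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        for s, gt in zip(samples, variant.gt_types):
            if gt == 1:
                counts[s] = 1
            elif gt == 3:
                counts[s] = 2
        for entry in str(csq).split(","):
            fields = entry.split("|")
            if len(fields) < len(fmt):
                fields += [""] * (len(fmt) - len(fields))
            af_raw = fields[idx[af_field]]
            symbol = fields[idx["SYMBOL"]] or None
            records.append(AnnotatedVariant(
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref=str(variant.REF),
                alt=str(variant.ALT[0]) if variant.ALT else "",
                gene=symbol,
                consequences=tuple(t for t in fields[idx["Consequence"]].split("&") if t),
                canonical=fields[idx["CANONICAL"]] == "YES",
                allele_frequency=float(af_raw) if af_raw not in ("", ".") else None,
                allele_counts=counts,
            ))
    return records


def read_variant_table(path: str | Path, sep: str = "\t",
                       columns: Mapping[str, str] | None = None):
    """Read annotated variants from a flat TSV (one row per record-sample).

    ``columns`` remaps the expected logical names (chrom, pos, ref, alt,
    sample, gene, consequence, af, canonical, allele_count) onto the file's
    header names. Rows sharing (chrom, pos, ref, alt, gene, consequence)
    are merged into one record accumulating per-sample counts. Consequence
    terms are ``&``-separated as in VEP output.
    """
    from .variant_prioritization import AnnotatedVariant

    logical = ["chrom", "pos", "ref", "alt", "sample", "gene", "consequence",
               "af", "canonical", "allele_count"]
    colmap = {k: k for k in logical}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [colmap[k] for k in logical if colmap[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns: {missing}")
    grouped: dict[tuple, dict] = {}
    for _, row in df.iterrows():
        gene = row[colmap["gene"]] or None
        cons = tuple(t for t in row[colmap["consequence"]].split("&") if t)
        key = (row[colmap["chrom"]], int(row[colmap["pos"]]),
               row[colmap["ref"]], row[colmap["alt"]], gene, cons)
        af_raw = row[colmap["af"]]
        rec = grouped.setdefault(key, {
            "af": float(af_raw) if af_raw not in ("", ".") else None,
            "canonical": row[colmap["canonical"]] in ("YES", "1", "true", "True"),
            "counts": {},
        })
        count = int(row[colmap["allele_count"]])
        if count:
            rec["counts"][row[colmap["sample"]]] = count
    return [
        AnnotatedVariant(chrom=k[0], pos=k[1], ref=k[2], alt=k[3], gene=k[4],
                         consequences=k[5], canonical=v["canonical"],
                         allele_frequency=v["af"], allele_counts=v["counts"])
        for k, v in grouped.items()
    ]


# ---------------------------------------------------------------------------
# sample alignment


def align_samples(blocks: Iterable[OmicsBlock], table: SampleTable
                  ) -> tuple[list[OmicsBlock], SampleTable]:
    """Reindex all blocks and the sample table to one shared sample order.

    The order of the sample table is taken as canonical; every block must
    contain exactly the same sample set.
    """
    order = list(table.samples)
    aligned = [b.reindex_samples(order) for b in blocks]
    for b in aligned:
        assert b.samples == order
    return aligned, table
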
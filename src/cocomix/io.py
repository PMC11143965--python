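"""File readers and writers for every pipeline artifact.

Formats: TSV count matrices (genes in rows, header of sample ids) with a CSV
sample-metadata sidecar; CSV composition tables; CSV secretome panels; GMT
gene-set collections; multi-channel TIFF micrographs with channel roles
stored in the image description. Write -> read round-trips are identities.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    COMPOSITION_COLUMNS,
    ExpressionMatrix,
    SecretomePanel,
    SpheroidImage,
    validate_composition,
)
from .downstream import GeneSetCollection
from .errors import ParseError

__all__ = [
    "read_counts", "write_counts",
    "read_composition", "write_composition",
    "read_panel", "write_panel",
    "read_gmt", "write_gmt",
    "read_image", "write_image",
]

_META_COLUMNS = ["role", "pair_id", "sc_culture_id", "fb_culture_id"]


def _meta_path(counts_path) -> Path:
    p = Path(counts_path)
    return p.with_suffix(p.suffix + ".samples.csv")


def write_counts(matrix: ExpressionMatrix, path, meta_path=None) -> None:
    matrix.validate()
    path = Path(path)
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")
    meta = matrix.samples.reindex(columns=_META_COLUMNS, fill_value="")
    meta.to_csv(meta_path or _meta_path(path), index_label="sample_id")


def read_counts(path, meta_path=None) -> ExpressionMatrix:
    path = Path(path)
    try:
        counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    if counts.isna().any().any():
        row = counts.index[counts.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {row!r}")
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    if meta_path.exists():
        samples = pd.read_csv(meta_path, index_col="sample_id", keep_default_na=False)
    else:
        samples = pd.DataFrame(index=pd.Index(counts.columns, name="sample_id"))
    try:
        return ExpressionMatrix(counts.astype(np.int64), samples).validate()
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_composition(table: pd.DataFrame, path) -> None:
    validate_composition(table)
    table.loc[:, list(COMPOSITION_COLUMNS)].to_csv(path, index=False)


def read_composition(path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in COMPOSITION_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    try:
        return validate_composition(table)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_panel(panel: SecretomePanel, path, meta_path=None) -> None:
    panel.validate()
    path = Path(path)
    panel.values.to_csv(path, index_label="analyte")
    meta = panel.samples.reindex(columns=_META_COLUMNS, fill_value="")
    meta.to_csv(meta_path or _meta_path(path), index_label="sample_id")


def read_panel(path, meta_path=None) -> SecretomePanel:
    path = Path(path)
    values = pd.read_csv(path, index_col="analyte")
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate analyte {dup!r}")
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    if meta_path.exists():
        samples = pd.read_csv(meta_path, index_col="sample_id", keep_default_na=False)
    else:
        samples = pd.DataFrame(index=pd.Index(values.columns, name="sample_id"))
    try:
        return SecretomePanel(values.astype(float), samples).validate()
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(members) != len(set(members)):
                raise ParseError(f"{path}:{lineno}: duplicate member in set {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions).validate()


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_image(image: SpheroidImage, path) -> None:
    """Multi-channel 16-bit TIFF; channel roles and pixel size travel in the
    image description as JSON."""
    image.validate()
    roles = list(image.channels)
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    desc = json.dumps({"channel_roles": roles, "pixel_size": image.pixel_size})
    tifffile.imwrite(path, stack, description=desc)


def read_image(path) -> SpheroidImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        roles = meta["channel_roles"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing channel-role metadata") from exc
    if stack.ndim == 2:
        stack = stack[None]
    if len(roles) != stack.shape[0]:
        raise ParseError(f"{path}: {len(roles)} roles for {stack.shape[0]} channels")
    channels = {r: np.asarray(stack[i], dtype=float) for i, r in enumerate(roles)}
    return SpheroidImage(channels, pixel_size=meta.get("pixel_size")).validate()
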
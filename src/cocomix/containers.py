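"""Core in-memory containers.

The pipeline moves gene-level count data around as an :class:`ExpressionMatrix`:
a genes x samples integer table plus a per-sample metadata frame. Sample roles
follow the coculture study design:

``sc_single``
    pure Schwann-cell culture,
``fb_single``
    pure fibroblast culture,
``real``
    a physical SC-FB coculture,
``virtual``
    an in-silico mixture of the two contributing singles at the measured
    SC fraction (the "no interaction" null sample),
``tumor`` / ``spheroid``
    external validation samples.

Composition tables, secretome panels and spheroid images have their own light
wrappers below. Validation is explicit (``validate()``) so file readers and
simulators can share it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

SAMPLE_ROLES = ("sc_single", "fb_single", "real", "virtual", "tumor", "spheroid")

#: required columns of a composition table
COMPOSITION_COLUMNS = ("coculture_id", "sc_culture_id", "fb_culture_id", "sc_fraction")


@dataclass
class ExpressionMatrix:
    """Gene x sample count table with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one integer column per sample.
    samples
        DataFrame indexed by sample id, aligned with ``counts.columns``.
        Expected columns: ``role`` plus, for cocultures, ``pair_id``,
        ``sc_culture_id`` and ``fb_culture_id``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> "ExpressionMatrix":
        if list(self.counts.columns) != list(self.samples.index):
            raise ValidationError("counts columns and sample metadata index differ")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if "role" in self.samples.columns:
            bad = set(self.samples["role"]) - set(SAMPLE_ROLES)
            if bad:
                raise ValidationError(f"unknown sample roles: {sorted(bad)}")
        return self

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            self.counts[sample_ids].copy(), self.samples.loc[sample_ids].copy()
        )

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])

    def concat(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        if not self.counts.index.equals(other.counts.index):
            raise ValidationError("gene universes differ; cannot concatenate")
        return ExpressionMatrix(
            pd.concat([self.counts, other.counts], axis=1),
            pd.concat([self.samples, other.samples], axis=0),
        ).validate()


def validate_composition(table: pd.DataFrame) -> pd.DataFrame:
    """Check a composition table (one row per coculture, SC fraction in [0, 1])."""
    missing = [c for c in COMPOSITION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"composition table missing columns: {missing}")
    p = table["sc_fraction"].to_numpy(dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("sc_fraction must lie in [0, 1]")
    if table["coculture_id"].duplicated().any():
        dup = table.loc[table["coculture_id"].duplicated(), "coculture_id"].iloc[0]
        raise ValidationError(f"duplicate coculture id: {dup!r}")
    return table


@dataclass
class SecretomePanel:
    """Analyte x sample concentration table (pg/mL; NaN = out of assay range)."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> "SecretomePanel":
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("panel columns and sample metadata index differ")
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v, initial=0.0) < 0:
            raise ValidationError("concentrations must be >= 0 or NaN")
        return self

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])


@dataclass
class SpheroidImage:
    """Multi-channel 2D micrograph with channel roles.

    ``channels`` maps a role (``phase``, ``live``, ``dead``, ``nuclei``) to a
    2D non-negative intensity array; all channels share one shape.
    ``pixel_size`` is the edge length of one pixel in micrometres, if known.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def validate(self) -> "SpheroidImage":
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"channel shapes differ: {shapes}")
        for role, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValidationError(f"channel {role!r} is not 2D")
            if (np.asarray(ch) < 0).any():
                raise ValidationError(f"channel {role!r} has negative intensities")
        return self

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruth:
    """What the simulator injected, for recovery scoring.

    ``log2fc`` is the true real-vs-virtual log2 fold change per gene
    (0 outside ``interaction_genes``); ``compositions`` echoes the per-
    coculture SC fraction actually drawn.
    """

    interaction_genes: list[str]
    log2fc: pd.Series
    compositions: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)
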
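"""Planted ground truth emitted by every generator.

A :class:`TruthBundle` carries the labels the generators planted (cell
identities, doublet/low-quality flags, per-variant provenance, true
concentrations, true kinetic rates). Pipeline operations never read it;
tests compare recovered quantities against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class TruthBundle:
    """Ground-truth sidecar for one generated dataset.

    Attributes
    ----------
    cells
        Per-cell table indexed by barcode with at least ``population``,
        ``is_doublet`` and ``is_lowquality`` columns (scRNA-seq scenarios).
    variants
        Per-variant provenance: class (sbs/dbs/indel/artifact), signature of
        origin, planted strand orientation, artifact reason.
    concentrations
        Per-sample true concentrations (chemistry scenarios).
    rates
        True scalar parameters (e.g. planted reaction slope), free-form.
    """

    cells: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None
    concentrations: pd.DataFrame | None = None
    rates: dict = field(default_factory=dict)

    def to_csv(self, prefix: str) -> list[str]:
        """Write each populated table as ``<prefix>.<name>.csv``; return paths."""
        written = []
        for name in ("cells", "variants", "concentrations"):
            table = getattr(self, name)
            if table is not None:
                path = f"{prefix}.{name}.csv"
                table.to_csv(path)
                written.append(path)
        return written
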
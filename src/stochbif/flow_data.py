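"""Data model and I/O for binned flow-cytometry fluorescence histograms.

A flow cytometer reports, for every acquired event, the fluorescence channel
(an integer bin index logarithmically related to real intensity) in which the
event fell.  Experiments here are organised as one histogram of channel counts
per (pregrowth condition, biological replicate, inducer concentration).

Channels are 1-based: channel ``c`` covers the half-open real interval
``[c - 0.5, c + 0.5)``.  All model fitting elsewhere in this package operates
directly in channel coordinates (log-intensity space);
:func:`channel_to_intensity` exists only for reporting on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChannelTransform",
    "ChannelHistogram",
    "Dataset",
    "PREGROWTHS",
    "channel_to_intensity",
    "to_density",
    "read_dataset",
    "write_dataset",
]

#: Recognised pregrowth (pre-induction culture history) labels:
#: ``"gal"`` = induced start, ``"raf"`` = uninduced (raffinose) start.
PREGROWTHS = ("gal", "raf")


@dataclass(frozen=True)
class ChannelTransform:
    """Log mapping between channel index and relative fluorescence intensity.

    Parameters
    ----------
    n_channels
        Number of channels (bins) on the instrument, default 1024.
    decades
        log10 dynamic range spanned by the channels, default 4 (channel
        ``n_channels`` is ``10**decades`` times the intensity of channel 1).
    """

    n_channels: int = 1024
    decades: float = 4.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")
        if not self.decades > 0:
            raise ValueError(f"decades must be > 0, got {self.decades}")


def channel_to_intensity(c, transform: ChannelTransform = ChannelTransform()):
    """Relative fluorescence intensity of channel coordinate ``c``.

    ``I(c) = 10 ** (decades * (c - 1) / (n_channels - 1))`` so that
    ``I(1) == 1``.  Real-valued ``c`` is allowed (interpolated coordinate).

    Raises
    ------
    ValueError
        If ``c`` lies outside ``[1, n_channels]``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 1) or np.any(c > transform.n_channels):
        raise ValueError(
            f"channel coordinate outside [1, {transform.n_channels}]"
        )
    out = 10.0 ** (transform.decades * (c - 1.0) / (transform.n_channels - 1.0))
    return out if out.ndim else float(out)


@dataclass
class ChannelHistogram:
    """Event counts over fluorescence channels for one experimental condition.

    Attributes
    ----------
    counts
        Non-negative integer vector, one entry per channel (channel 1 first).
    concentration
        Galactose concentration in % weight/volume.
    replicate_id
        Biological replicate label.
    pregrowth
        One of :data:`PREGROWTHS`.
    """

    counts: np.ndarray
    concentration: float
    replicate_id: str = "1"
    pregrowth: str = "gal"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pregrowth not in PREGROWTHS:
            raise ValueError(f"pregrowth must be one of {PREGROWTHS}")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        self.counts = counts

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        """Total number of events in the histogram."""
        return int(self.counts.sum())

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.pregrowth, self.replicate_id, self.concentration)


def to_density(h: ChannelHistogram) -> np.ndarray:
    """Per-channel event fractions (sum to one) of a histogram."""
    total = h.total
    if total <= 0:
        raise ValueError("cannot normalise a histogram with zero total count")
    return h.counts / total


@dataclass
class Dataset:
    """Collection of histograms from one experiment, sharing a channel axis."""

    histograms: dict[tuple[str, str, float], ChannelHistogram] = field(
        default_factory=dict
    )
    transform: ChannelTransform = ChannelTransform()

    def __post_init__(self) -> None:
        for key, h in self.histograms.items():
            if key != h.key:
                raise ValueError(f"histogram keyed {key} reports key {h.key}")
            if h.n_channels != self.transform.n_channels:
                raise ValueError(
                    f"histogram {key} has {h.n_channels} channels, "
                    f"dataset transform expects {self.transform.n_channels}"
                )

    def __len__(self) -> int:
        return len(self.histograms)

    def __iter__(self) -> Iterator[ChannelHistogram]:
        return iter(self.histograms.values())

    def add(self, h: ChannelHistogram) -> None:
        if h.key in self.histograms:
            raise ValueError(f"duplicate histogram key {h.key}")
        if h.n_channels != self.transform.n_channels:
            raise ValueError("channel count does not match dataset transform")
        self.histograms[h.key] = h

    def get(self, pregrowth: str, replicate_id: str, concentration: float
            ) -> ChannelHistogram:
        return self.histograms[(pregrowth, replicate_id, concentration)]

    def pregrowths(self) -> list[str]:
        return sorted({k[0] for k in self.histograms})

    def replicates(self, pregrowth: str) -> list[str]:
        return sorted({k[1] for k in self.histograms if k[0] == pregrowth})

    def concentrations(self, pregrowth: str | None = None,
                       replicate_id: str | None = None) -> list[float]:
        keys = [
            k for k in self.histograms
            if (pregrowth is None or k[0] == pregrowth)
            and (replicate_id is None or k[1] == replicate_id)
        ]
        return sorted({k[2] for k in keys})

    def subset(self, pregrowth: str | None = None,
               replicate_id: str | None = None,
               concentrations: list[float] | None = None) -> "Dataset":
        """New dataset restricted to the matching condition keys."""
        conc = None if concentrations is None else set(concentrations)
        kept = {
            k: h for k, h in self.histograms.items()
            if (pregrowth is None or k[0] == pregrowth)
            and (replicate_id is None or k[1] == replicate_id)
            and (conc is None or k[2] in conc)
        }
        return Dataset(histograms=kept, transform=self.transform)


# --------------------------------------------------------------------------
# TSV table format: header `channel<TAB>pregrowth:replicate:concentration...`,
# one data row per channel, condition columns in lexicographic order.
# --------------------------------------------------------------------------

def _format_concentration(g: float) -> str:
    return format(g, ".10g")


def _column_name(key: tuple[str, str, float]) -> str:
    pregrowth, replicate_id, concentration = key
    return f"{pregrowth}:{replicate_id}:{_format_concentration(concentration)}"


def _parse_column(name: str) -> tuple[str, str, float]:
    parts = name.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"malformed condition column {name!r}; "
            "expected 'pregrowth:replicate:concentration'"
        )
    pregrowth, replicate_id, conc = parts
    if pregrowth not in PREGROWTHS:
        raise ValueError(f"unknown pregrowth {pregrowth!r} in column {name!r}")
    try:
        concentration = float(conc)
    except ValueError as exc:
        raise ValueError(f"bad concentration in column {name!r}") from exc
    return pregrowth, replicate_id, concentration


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset to the TSV histogram table format.

    Columns are sorted lexicographically so repeated writes of the same
    dataset are byte-identical.
    """
    names = sorted(_column_name(k) for k in dataset.histograms)
    by_name = {_column_name(k): h for k, h in dataset.histograms.items()}
    # An empty dataset writes a header-only table.
    n_rows = dataset.transform.n_channels if names else 0
    table = pd.DataFrame({"channel": np.arange(1, n_rows + 1)})
    for name in names:
        table[name] = by_name[name].counts
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_dataset(path: str | Path,
                 transform: ChannelTransform | None = None) -> Dataset:
    """Read a histogram table written by :func:`write_dataset`.

    Raises
    ------
    ValueError
        On malformed/duplicate condition columns or negative / non-integer
        counts.
    """
    table = pd.read_csv(path, sep="\t")
    if table.columns[0] != "channel":
        raise ValueError("first column of a histogram table must be 'channel'")
    n_channels = len(table)
    if transform is None:
        transform = (
            ChannelTransform(n_channels=n_channels) if n_channels >= 2
            else ChannelTransform()
        )
    if n_channels and n_channels != transform.n_channels:
        raise ValueError(
            f"table has {n_channels} rows, transform expects "
            f"{transform.n_channels} channels"
        )
    dataset = Dataset(transform=transform)
    seen: set[tuple[str, str, float]] = set()
    for name in table.columns[1:]:
        key = _parse_column(str(name))
        if key in seen:
            raise ValueError(f"duplicate condition column {name!r}")
        seen.add(key)
        values = table[name].to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.array_equal(values, np.rint(values)):
                raise ValueError(f"non-integer count in column {name!r}")
            values = np.rint(values).astype(np.int64)
        if np.any(values < 0):
            raise ValueError(f"negative count in column {name!r}")
        dataset.add(ChannelHistogram(
            counts=values,
            concentration=key[2],
            replicate_id=key[1],
            pregrowth=key[0],
        ))
    return dataset
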
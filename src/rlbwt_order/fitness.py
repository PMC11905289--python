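"""The optimization objective: byte-pair RLE size of the BWT.

The alphabet-ordering problem minimizes the stored size of the run-length
encoded BWT, not the run count r: memory is what matters, and a run longer
than 255 costs extra pairs.  The sentinel's run is part of the compressed
size; the uncompressed size is the raw file length (no sentinel).  Results
are also reported as the signed percentage change

    C = (compressed - uncompressed) / uncompressed * 100,

negative when the encoding is smaller than the input.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import AlphabetOrdering, as_bytes
from .bwt_core import bwt
from .rle import encoded_size, runs

__all__ = ["FitnessRecord", "fitness", "percent_change", "fitness_record"]


@dataclass(frozen=True)
class FitnessRecord:
    """Compressed/uncompressed byte sizes and their percentage change."""

    compressed_bytes: int
    uncompressed_bytes: int

    @property
    def percent_change(self) -> float:
        return percent_change(self.compressed_bytes, self.uncompressed_bytes)


def fitness(
    text: str | bytes, ordering: AlphabetOrdering | None = None
) -> int:
    """Byte-pair RLE size of the sentinel-appended BWT under ``ordering``.

    This is the quantity the search minimizes; one call is one objective
    evaluation ("step") in search accounting.
    """
    return encoded_size(runs(bwt(text, ordering).L))


def percent_change(compressed: int, uncompressed: int) -> float:
    """Signed percentage size change; negative means a size reduction."""
    if uncompressed <= 0:
        raise ValueError("uncompressed size must be positive")
    return (compressed - uncompressed) / uncompressed * 100.0


def fitness_record(
    text: str | bytes, ordering: AlphabetOrdering | None = None
) -> FitnessRecord:
    """Fitness plus the percentage change against the raw text length."""
    data = as_bytes(text)
    return FitnessRecord(fitness(data, ordering), len(data))
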
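"""Default ACSS-MH subscale map.

SYNTHETIC STAND-IN: the published item-to-dimension key of the 31-item
continuity scale is not redistributable, so this default partitions the
items into the three named dimensions by consecutive blocks, and defines a
relational-base analysis subscale as a subset of the individualized-care
block.  Replace it with the licensed key (via a YAML config, see
:func:`carenet.patient_scores.load_subscale_map`) for any substantive use;
totals and all scoring arithmetic are unaffected by the map.
"""

from __future__ import annotations

#: Three dimensions partitioning items 1..31, plus the relational-base
#: analysis subscale (a subset, not part of the partition).
DEFAULT_SUBSCALE_MAP: dict[str, list[int]] = {
    "individualized_care": list(range(1, 12)),       # items 1-11
    "system_responsiveness": list(range(12, 22)),    # items 12-21
    "carer_responsiveness": list(range(22, 32)),     # items 22-31
    "relational_base": list(range(1, 9)),            # items 1-8 (analysis subset)
}

#: The subscales forming a partition of all 31 items (used by the
#: partition-consistency check; relational_base overlaps by design).
PARTITION_SUBSCALES: tuple[str, ...] = (
    "individualized_care",
    "system_responsiveness",
    "carer_responsiveness",
)
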
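"""Small packaged datasets."""

from __future__ import annotations

from importlib import resources

from .screen_io import LoadReport, TargetAnnotationTable, read_annotations

__all__ = ["load_gsk3b_inhibitors"]


def load_gsk3b_inhibitors() -> tuple[TargetAnnotationTable, LoadReport]:
    """Six GSK3β small-molecule inhibitors with their GSK3β pIC50 values.

    CHIR99021 ("CHIRON"), 6-bromoindirubin-3'-oxime ("6BIO") and four
    AstraZeneca compounds (AZ1–AZ4); GSK3β is each compound's primary
    target.  Useful as a tiny real-world-shaped annotation table.
    """
    path = resources.files("mmpscreen.data") / "gsk3b_inhibitors.tsv"
    with resources.as_file(path) as p:
        return read_annotations(p)
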
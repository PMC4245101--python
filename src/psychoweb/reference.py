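"""Published reference assignments for the 55-item CPRS symptom web.

The package ships the published item-level comparison table for the
optimal six-cluster solution of the CPRS psychopathology network: for each
of the 55 items retained in the accepted web, the principal component it
was assigned to by the forced-choice filter and the network cluster it was
placed in by community detection. Five items sit on cluster/component
boundaries ("border disputes") and differ between the two sides.

These assignments serve as a fixed desk-check input: the mismatch
arithmetic of :mod:`psychoweb.optimize` can be verified against the
published per-pair scores without access to the underlying patient data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .partition import Partition

__all__ = ["load_cprs_reference", "reference_partitions"]


def load_cprs_reference() -> pd.DataFrame:
    """Item table: item label, symptom name, component and cluster labels."""
    with resources.files("psychoweb.data").joinpath("cprs_web_assignments.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)


def reference_partitions() -> tuple[Partition, Partition]:
    """(network clusters, forced-choice components) over the 55 retained items."""
    df = load_cprs_reference()
    ncs = Partition({r.item: r.cluster for r in df.itertuples()})
    pcs = Partition({r.item: r.component for r in df.itertuples()})
    return ncs, pcs
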
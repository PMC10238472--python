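import numpy as np
import pandas as pd
import pytest

from psdpharm.containers import PeptideMatrix


def build_matrix(
    abundance: np.ndarray,
    channels: list[tuple[str, str, str | None]],
    peptides: list[str] | None = None,
    pep2prot: dict[str, tuple[str, ...]] | None = None,
) -> PeptideMatrix:
    """Hand-build a PeptideMatrix.

    ``channels`` is a list of (channel_key, plex, sample_id-or-None);
    None marks a pooled channel.
    """
    abundance = np.asarray(abundance, dtype=float)
    n_pep = abundance.shape[0]
    if peptides is None:
        peptides = [f"pep{i + 1}" for i in range(n_pep)]
    keys = [c[0] for c in channels]
    meta = pd.DataFrame(
        {
            "plex": [c[1] for c in channels],
            "channel": [c[0].split(".")[-1] for c in channels],
            "sample_id": [c[2] for c in channels],
            "is_pooled": [c[2] is None for c in channels],
        },
        index=pd.Index(keys, name="channel_key"),
    )
    if pep2prot is None:
        pep2prot = {p: (f"prot_{p}",) for p in peptides}
    return PeptideMatrix(
        abundance=pd.DataFrame(abundance, index=pd.Index(peptides), columns=keys),
        channel_meta=meta,
        pep2prot=pd.Series([pep2prot[p] for p in peptides], index=pd.Index(peptides)),
    )


@pytest.fixture
def two_plex_matrix() -> PeptideMatrix:
    """2 peptides x (2 subjects + 2 pooled) x 2 plexes."""
    channels = [
        ("P1.C01", "P1", "S1"),
        ("P1.C02", "P1", "S2"),
        ("P1.C12", "P1", None),
        ("P1.C13", "P1", None),
        ("P2.C01", "P2", "S3"),
        ("P2.C02", "P2", "S4"),
        ("P2.C12", "P2", None),
        ("P2.C13", "P2", None),
    ]
    ab = np.array(
        [
            [90.0, 110.0, 100.0, 120.0, 190.0, 210.0, 200.0, 220.0],
            [9.0, 11.0, 10.0, 12.0, 19.0, 21.0, 20.0, 22.0],
        ]
    )
    return build_matrix(ab, channels)
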
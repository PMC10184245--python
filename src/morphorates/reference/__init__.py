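"""Packaged reference tables."""

from importlib import resources

import pandas as pd

__all__ = ["load_region_summary"]


def load_region_summary() -> pd.DataFrame:
    """Published per-region cranial summary statistics.

    Seventeen placental cranial regions labelled by embryonic origin
    (12 cranial-neural-crest, 5 paraxial-mesoderm) with their reported
    multivariate phylogenetic signal (K_mult), allometry effect size
    (Z), Procrustes-variance disparity and net evolutionary rate (in
    the source's printed units).  Significance-marker columns carry an
    asterisk where the source reports p < 0.01.
    """
    with resources.files(__name__).joinpath(
            "placental_cranial_regions.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    return df
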
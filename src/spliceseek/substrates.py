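"""Reference substrate polypeptides used in published splicing digests.

Region coordinates in the names refer to the parent antigen sequence
(human gp100/PMEL17 melanocyte protein, HIV gag-pol, MCMV pp89); local
fragment coordinates inside this package are always 1-based on the
substrate itself.
"""

from __future__ import annotations

from .enumeration import Substrate

# 13C6-lysine and 15N-leucine mass offsets for heavy analogues.
DELTA_13C6_LYS = 6.02013
DELTA_15N_LEU = 0.99703

BUNDLED_SUBSTRATES: dict[str, Substrate] = {
    s.id: s
    for s in (
        Substrate("gp100_40-52", "RTKAWNRQLYPEW"),
        Substrate("gp100_35-57", "VSRQLRTKAWNRQLYPEWTEAQR"),
        Substrate("gp100_201-230", "AHSSSAFTITDQVPFSVSVSQLRALDGGNK"),
        Substrate("gagpol_29-58", "YKLKHIVWASRELERFAVNPGLLEVTSEGC"),
        Substrate("pp89_16-40", "RLMYDMYPHFMPTNLGPSEKRVWMS"),
    )
}


def heavy_analogue(substrate: Substrate, labels: dict[str, float] | None = None) -> Substrate:
    """A label-carrying copy: every residue in ``labels`` gets its offset.

    Default labelling is 13C6 on K and 15N on L, matching the heavy
    substrate used to diagnose trans splicing.
    """
    labels = labels if labels is not None else {"K": DELTA_13C6_LYS, "L": DELTA_15N_LEU}
    offsets = {
        pos: labels[aa]
        for pos, aa in enumerate(substrate.sequence, start=1)
        if aa in labels
    }
    return Substrate(substrate.id + "_heavy", substrate.sequence, offsets)
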
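"""Shared dataset definition for the numbered analysis scripts.

One synthetic binding-mode study at desk scale: 5 replicas x 400 frames at
1 ns spacing (a scaled-down analogue of a 20-replica design), with the
default planted interaction probabilities, 80% conserved-water-site
occupancy, ~12 exchanging waters per replica and a 70% native Thr58
schedule. Every script regenerates it deterministically from the same seed.
"""

from pathlib import Path

import bindmode as bm

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"


def dataset():
    cfg = bm.GeneratorConfig(n_replicas=5, n_frames=400, n_waters=40,
                             water_exchange_rate=12.0, seed=SEED)
    return bm.simulate(cfg)


def water_site(topo):
    from bindmode.water import WaterSite, sidechain_anchor
    return WaterSite(anchor_selections=(sidechain_anchor(topo, 58),
                                        sidechain_anchor(topo, 10)))
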
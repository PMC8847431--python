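"""End-to-end acquisition pipelines.

``simulate_and_select`` runs the Monte Carlo one acquisition angle at a
time, groups coincidences and applies the mode selection immediately,
keeping only the (small) selected-event tables in memory.  This is the
recommended path for realistic exposures, where the raw hit list of a
full multi-angle run can reach tens of millions of rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import events as ev
from . import geometry as geo
from . import simulator as sim


def simulate_and_select_multi(
    sources,
    setup: geo.AcquisitionSetup,
    selections,
    duration_s: float,
    rng=None,
    seed=None,
    phantoms=(),
    blur: bool = True,
    scatter_mode: str = "narrow",
    window_ns: float = ev.DEFAULT_COINCIDENCE_WINDOW_NS,
):
    """Simulate once and select several (mode, target) pairs at once.

    Returns ``(selected, emitted)`` where ``selected`` maps each
    ``(mode, target)`` pair to its event table.  Event selection is
    per modality over the same list-mode stream, mirroring how the
    modes are chosen after the measurement.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    poses = dict(geo.build_multi_angle(setup))
    selected_frames = {key: [] for key in selections}
    emitted_frames = []
    for angle_id, cams in geo.build_multi_angle(setup):
        single = geo.AcquisitionSetup(
            cameras=cams, angles_deg=(0.0,), ring_diameter=setup.ring_diameter
        )
        res = sim.simulate_acquisition(
            sources, single, phantoms=phantoms, duration_s=duration_s,
            rng=rng, blur=blur, scatter_mode=scatter_mode,
        )
        hits = ev.group_coincidences(res.hits, window_ns)
        local_poses = {0: poses[angle_id]}
        for mode, target in selections:
            if mode == "compton":
                sel = ev.select_compton(hits, local_poses, target)
            elif mode == "pinhole":
                sel = ev.select_pinhole(hits, target)
            elif mode == "pet":
                sel = ev.select_pet(hits, local_poses, target)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            sel["angle_id"] = angle_id
            selected_frames[(mode, target)].append(sel)
        emi = res.emitted.copy()
        emi["angle_id"] = angle_id
        emitted_frames.append(emi)
        del res, hits
    selected = {key: pd.concat(v, ignore_index=True)
                for key, v in selected_frames.items()}
    emitted = pd.concat(emitted_frames, ignore_index=True)
    return selected, emitted


def simulate_and_select(sources, setup, mode, target, duration_s, **kwargs):
    """Single-modality convenience wrapper of
    :func:`simulate_and_select_multi`."""
    selected, emitted = simulate_and_select_multi(
        sources, setup, [(mode, target)], duration_s, **kwargs
    )
    return selected[(mode, target)], emitted


def emitted_photons(emitted: pd.DataFrame, energy_kev: float, tol: float = 1.0) -> int:
    m = np.abs(emitted["energy_kev"] - energy_kev) < tol
    return int(emitted.loc[m, "n_photons"].sum())
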
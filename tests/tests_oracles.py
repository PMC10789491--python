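"""Independent brute-force oracles shared by the test modules."""
import numpy as np


def brute_force_neighbours(world, cell_id):
    """All-pairs contact scan, independent of the k-d-tree path."""
    idx = world.live()
    i = world.index_of[cell_id]
    radii = world.radii(idx)
    cf = world.config.geometry.contact_factor
    ri = radii[int(np.flatnonzero(idx == i)[0])]
    out = []
    for row, j in enumerate(idx):
        if j == i:
            continue
        d = np.linalg.norm(world.pos[j] - world.pos[i])
        if d < (radii[row] + ri) * cf:
            out.append(int(world.cell_id[j]))
    return sorted(out)
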
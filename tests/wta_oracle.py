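"""Independent brute-force oracle for contiguous winner-take-all selection.

Pure-python reference kept deliberately free of the package's implementation
(no scipy labelling): enumerate the threshold set, flood-fill the component
containing the argmax by hand.
"""

from __future__ import annotations


def oracle_theta_wta(grid, theta, mask=None, connectivity=8):
    """Return (region frozenset, peak) or (frozenset(), None) for no winner."""
    rows = len(grid)
    cols = len(grid[0])
    admissible = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if mask is None or mask[r][c]
    ]
    if not admissible:
        raise ValueError("empty mask")
    peak = None
    best = None
    for r, c in admissible:  # admissible is in row-major order: first max wins
        if best is None or grid[r][c] > best:
            best = grid[r][c]
            peak = (r, c)
    if best is None or best <= 0:
        return frozenset(), None
    thresh = (1.0 - theta) * best
    candidates = {(r, c) for r, c in admissible if grid[r][c] >= thresh - 1e-12}
    if connectivity == 8:
        offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    region = {peak}
    stack = [peak]
    while stack:
        r, c = stack.pop()
        for dr, dc in offs:
            q = (r + dr, c + dc)
            if q in candidates and q not in region:
                region.add(q)
                stack.append(q)
    return frozenset(region), peak
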
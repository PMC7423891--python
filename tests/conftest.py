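import numpy as np
import pytest

from mtwedge.params import ModelParameters


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def templates(params):
    from mtwedge.engine import TemplateSet
    return TemplateSet.build(params)


def flood_fill_clusters(config, seam="shifted"):
    """Independent flood-fill oracle for connected uncompressed-dimer islands."""
    grid = config.composition
    nr, npf = grid.shape
    seen = np.zeros_like(grid, dtype=bool)
    out = []

    def neighbours(r, k):
        res = []
        for dr in (-1, 1):
            if 0 <= r + dr < nr:
                res.append((r + dr, k))
        if k + 1 < npf:
            res.append((r, k + 1))
        if k - 1 >= 0:
            res.append((r, k - 1))
        if seam == "shifted":
            if k == npf - 1:
                for dr in (1, 2):
                    if r + dr < nr:
                        res.append((r + dr, 0))
            if k == 0:
                for dr in (1, 2):
                    if r - dr >= 0:
                        res.append((r - dr, npf - 1))
        elif seam == "wrap":
            if k == npf - 1:
                res.append((r, 0))
            if k == 0:
                res.append((r, npf - 1))
        return res

    for r in range(nr):
        for k in range(npf):
            if grid[r, k] and not seen[r, k]:
                stack = [(r, k)]
                seen[r, k] = True
                comp = []
                while stack:
                    cell = stack.pop()
                    comp.append(cell)
                    for nb in neighbours(*cell):
                        if grid[nb] and not seen[nb]:
                            seen[nb] = True
                            stack.append(nb)
                out.append(sorted(comp))
    out.sort(key=lambda c: c[0])
    return out
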
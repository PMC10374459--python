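import numpy as np
import pytest

from macnuc import NucleusSpec, render_silhouette


@pytest.fixture
def sphere_spec():
    """Single 15 μm-radius node, volume 4/3·π·15³ ≈ 14137.2 μm³."""
    return NucleusSpec(node_radii=(15.0,))


@pytest.fixture
def chain_spec():
    """8-node chain emulating the in-vivo geometry (~420 μm long)."""
    return NucleusSpec(node_radii=(15.0,) * 8, gap_lengths=(20.0,) * 7,
                       connector_radius_um=1.0)


@pytest.fixture
def two_node_spec():
    return NucleusSpec(node_radii=(10.0, 10.0), gap_lengths=(5.0,),
                       connector_radius_um=1.0)


@pytest.fixture
def sphere_mask(sphere_spec):
    return render_silhouette(sphere_spec, 0.5)


def random_spec(rng: np.random.Generator) -> NucleusSpec:
    """Random valid beads-on-string spec for oracle-equivalence checks."""
    n = int(rng.integers(1, 11))
    radii = tuple(rng.uniform(8.0, 18.0, size=n))
    gaps = tuple(rng.uniform(0.0, 25.0, size=n - 1)) if n > 1 else ()
    r_c = float(rng.uniform(0.5, min(2.0, 0.9 * min(radii))))
    return NucleusSpec(node_radii=radii, gap_lengths=gaps, connector_radius_um=r_c)
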
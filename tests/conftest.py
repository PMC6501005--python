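import numpy as np
import pytest
from scipy import ndimage

from periscope.genome import GenomeModel
from periscope.radial import NucleusRecord
from periscope.simulate import NucleusSimParams, make_nucleus_image


@pytest.fixture
def toy_genome():
    """2.5-Mb single-chromosome genome: windows [0,1e6), [1e6,2e6), [2e6,2.5e6)."""
    return GenomeModel.from_dict({"chr1": 2_500_000})


@pytest.fixture
def two_chrom_genome():
    return GenomeModel.from_dict({"chr1": 2_000_000, "chr2": 2_000_000})


def nucleus_record(params: NucleusSimParams) -> tuple[NucleusRecord, dict]:
    """Render one synthetic nucleus and wrap it as a NucleusRecord."""
    image, mask, truth = make_nucleus_image(params)
    cr, cc = ndimage.center_of_mass(mask)
    return NucleusRecord(1, image, mask, (cr, cc)), truth


@pytest.fixture
def ring_nucleus():
    """Noiseless hard-edged ring fixture: base 100, contrast 4 from radius 0.75."""
    params = NucleusSimParams(
        noise_sd=0.0, ring_contrast=4.0, ring_start=0.75, edge_sigma=0.0,
        semi_axes=(60.0, 45.0),
    )
    return nucleus_record(params)


@pytest.fixture
def smooth_ring_nucleus():
    """Noiseless ring fixture at generator defaults (band-limited edge)."""
    params = NucleusSimParams(
        noise_sd=0.0, ring_contrast=4.0, ring_start=0.75, semi_axes=(60.0, 45.0)
    )
    return nucleus_record(params)


@pytest.fixture
def flat_nucleus():
    params = NucleusSimParams(noise_sd=0.0, ring_contrast=1.0, semi_axes=(50.0, 40.0))
    return nucleus_record(params)
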
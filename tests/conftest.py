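import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from xtalaudit.core import CrystalFrame
from xtalaudit.pdbio import AtomRecord, ModelEnsemble


def toy_atoms(n, frame, seed=0, elements=("C", "N", "O"), b_range=(10, 30)):
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n):
        el = str(rng.choice(elements))
        atoms.append(AtomRecord(
            serial=i + 1, name=el, altloc="", resname="ALA", chain="A",
            resseq=i + 1, icode="",
            xyz=frame.frac_to_cart(rng.uniform(0, 1, 3)),
            occupancy=1.0, b_iso=float(rng.uniform(*b_range)),
            u_aniso=None, element=el, scattering_type=el,
        ))
    return atoms


@pytest.fixture(scope="session")
def p1_frame():
    return CrystalFrame((14.0, 15.0, 13.0, 90.0, 90.0, 90.0), "P1")


@pytest.fixture(scope="session")
def p21_frame():
    return CrystalFrame((15.0, 16.0, 14.0, 90.0, 100.0, 90.0), "P21")


@pytest.fixture(scope="session")
def small_p1_ensemble(p1_frame):
    return ModelEnsemble(models=[toy_atoms(25, p1_frame, seed=11)],
                         frame=p1_frame)


@pytest.fixture(scope="session")
def small_p21_ensemble(p21_frame):
    return ModelEnsemble(models=[toy_atoms(25, p21_frame, seed=12)],
                         frame=p21_frame)
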
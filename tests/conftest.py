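import itertools

import numpy as np
import pytest

import isodecomp as iso
from isodecomp.spectra import Spectrum


@pytest.fixture(scope="session", autouse=True)
def element_x():
    """The two-isotope demonstration atom X (mass 1 at 20%, mass 2 at 80%)."""
    iso.register_element(iso.ElementRecord.from_pairs("X", iso.X_ISOTOPES))
    return iso.get_element("X")


@pytest.fixture(scope="session")
def exact():
    return iso.PruneConfig(eps_a=0.0, eps_m=0.0)


@pytest.fixture(scope="session")
def x10_x11(exact):
    """Patterns for the X10/X11 cluster pair used throughout."""
    return tuple(iso.species_pattern(iso.parse_formula(f), exact)
                 for f in ("X10", "X11"))


@pytest.fixture(scope="session")
def mixture_system(x10_x11):
    """Noiseless X10 (A=10) + X11 (A=20) mixture at R=100, m0=0, with its
    design matrix, on a 0.01 Th grid."""
    curves = iso.CalibrationCurves.from_resolution(100.0)
    axis = Spectrum.axis(8.0, 24.0, 0.01)
    pairs = list(zip(x10_x11, (10.0, 20.0)))
    s = iso.superpose(pairs, curves, axis, labels=("X10", "X11"))
    S = iso.build_design_matrix(x10_x11, curves, axis, labels=("X10", "X11"))
    return s, S, curves


def brute_force_power(masses, abundances, n):
    """Exhaustive isotopologue enumeration of an n-mer: the oracle for
    pattern_power with pruning disabled."""
    acc: dict[float, float] = {}
    for combo in itertools.product(range(len(masses)), repeat=n):
        m = sum(masses[i] for i in combo)
        a = 1.0
        for i in combo:
            a *= abundances[i]
        acc[m] = acc.get(m, 0.0) + a
    items = sorted(acc.items())
    return np.array([m for m, _ in items]), np.array([a for _, a in items])
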
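import numpy as np
import pytest

from ratpbpk.compound_model import CompoundRecord, InVitroInputs, IonizationProfile
from ratpbpk.ivive import RatPhysiologyConstants
from ratpbpk.physiology import default_physiology


@pytest.fixture(scope="session")
def phys():
    return default_physiology()


@pytest.fixture(scope="session")
def scaling_phys():
    return RatPhysiologyConstants()


def make_compound(
    compound_id="CPD001",
    logd74=2.0,
    s_aq=10.0,
    papp=1e-4,
    clint=10.0,
    fup=0.2,
    bp=1.0,
    mw=400.0,
    category="neutral",
    pka=None,
    s_fassif=None,
    s_fessif=None,
):
    """Hand-rolled compound factory for targeted scenarios."""
    if category == "neutral":
        ion = IonizationProfile(0.0, 0.0, 1.0, 0.0, ())
    elif category == "basic":
        pka = 9.0 if pka is None else pka
        f_cat = 1.0 / (1.0 + 10.0 ** (7.4 - pka))
        ion = IonizationProfile(0.0, f_cat, 1.0 - f_cat, 0.0, ((pka, "base"),))
    elif category == "acidic":
        pka = 4.5 if pka is None else pka
        f_an = 1.0 / (1.0 + 10.0 ** (pka - 7.4))
        ion = IonizationProfile(f_an, 0.0, 1.0 - f_an, 0.0, ((pka, "acid"),))
    else:
        raise ValueError(category)
    return CompoundRecord(
        compound_id=compound_id,
        in_vitro=InVitroInputs(
            logd74=logd74, s_aq=s_aq, papp_llcpk1=papp, clint_heps=clint,
            fup=fup, bp=bp, mw=mw, s_fassif=s_fassif, s_fessif=s_fessif,
        ),
        ionization=ion,
    )


@pytest.fixture
def neutral_compound():
    return make_compound()


@pytest.fixture
def basic_compound():
    return make_compound(compound_id="CPD002", category="basic", bp=1.2)
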
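import datetime as dt

import pytest

from pregclaims import CodeConfig
from pregclaims.deliveries import RawDeliveryCode


@pytest.fixture
def config() -> CodeConfig:
    return CodeConfig.default()


def drg(person: str, day: int, code: str = "O60A", base: dt.date = dt.date(2015, 1, 1)):
    term = {"O60A": "full_term", "O60B": "full_term", "O60C": "preterm",
            "O01A": "full_term", "O01C": "preterm"}[code]
    return RawDeliveryCode(person, base + dt.timedelta(days=day), "DRG", code, term)


def tarmed(person: str, day: int, base: dt.date = dt.date(2015, 1, 1)):
    return RawDeliveryCode(person, base + dt.timedelta(days=day), "TARMED", "DEL01", "unspecified")
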
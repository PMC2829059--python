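import pytest

from nhejsim import build_reporter, build_repeat_reporter, hindiii_fragment, \
    iscei_fragment, repeat_fragment
from nhejsim.profiles import default_profiles


@pytest.fixture(scope="session")
def gfp_reporter():
    return build_reporter(seed=1)


@pytest.fixture(scope="session")
def repeat_reporter():
    return build_repeat_reporter(seed=1)


@pytest.fixture(scope="session")
def hind_frag(gfp_reporter):
    record, layout = gfp_reporter
    return hindiii_fragment(record, layout)


@pytest.fixture(scope="session")
def iscei_frag(gfp_reporter):
    record, layout = gfp_reporter
    return iscei_fragment(record, layout)


@pytest.fixture(scope="session")
def repeat_frag(repeat_reporter):
    record, layout = repeat_reporter
    return repeat_fragment(record, layout)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()
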
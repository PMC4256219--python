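import pytest

from gofunsim import (
    fixture_F1,
    ic_annotation,
    ic_universal,
    ic_wang,
    ic_zhang,
)


@pytest.fixture(scope="session")
def f1():
    """The frozen six-term / five-protein worked fixture."""
    return fixture_F1()


@pytest.fixture(scope="session")
def f1_dag(f1):
    return f1[0]


@pytest.fixture(scope="session")
def f1_ann(f1):
    return f1[1]


@pytest.fixture(scope="session")
def f1_ic(f1):
    """Annotation-frequency IC table on the fixture corpus."""
    dag, ann = f1
    return ic_annotation(ann, dag)


@pytest.fixture(scope="session")
def f1_tables(f1):
    dag, ann = f1
    return {
        "annotation": ic_annotation(ann, dag),
        "zhang": ic_zhang(dag),
        "wang": ic_wang(dag),
        "universal": ic_universal(dag),
    }
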
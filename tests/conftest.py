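import pytest

from silacpipe.io_formats import ExperimentDesign

# per-pattern protein counts from the two published experiments, with the
# analysis totals (proteins quantified at least twice) used as divisors
TABLE1_COUNTS = {
    "P1": 4399,
    "P2": 40,
    "P3": 15,
    "P4": 2,
    "P5": 143,
    "P6": 8,
    "P7": 188,
    "P8": 8,
    "P9": 0,
}
TABLE1_TOTAL = 4633

TABLE2_COUNTS = {
    "P1": 3200,
    "P2": 282,
    "P3": 8,
    "P4": 66,
    "P5": 379,
    "P6": 913,
    "P7": 19,
    "P8": 413,
    "P9": 1,
}
TABLE2_TOTAL = 5471


@pytest.fixture
def design():
    return ExperimentDesign(
        experiment_label="toy",
        replicates=(("F1", "forward"), ("F2", "forward"), ("R1", "reverse")),
    )


@pytest.fixture
def table1():
    return dict(TABLE1_COUNTS), TABLE1_TOTAL


@pytest.fixture
def table2():
    return dict(TABLE2_COUNTS), TABLE2_TOTAL
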
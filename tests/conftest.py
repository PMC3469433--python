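import pytest

from sccoloc.geometry import FocusInterval, Label, Stretch, StretchSet


def iv(start, end, label=Label.GFP):
    return FocusInterval(start, end, label)


@pytest.fixture
def single_stretch():
    """One 10 µm stretch, one Zip3 focus [4, 5], one encompassed GFP focus."""
    return StretchSet(
        [
            Stretch(
                id="s1",
                length=10.0,
                zip3=[iv(4.0, 5.0, Label.ZIP3)],
                gfp=[iv(4.25, 4.75)],
            )
        ],
        name="single",
    )


@pytest.fixture
def three_stretch():
    """Three stretches with mixed Zip3 geometry and 6 GFP foci."""
    return StretchSet(
        [
            Stretch(
                id="a",
                length=8.0,
                zip3=[iv(1.0, 1.6, Label.ZIP3), iv(5.0, 5.4, Label.ZIP3)],
                gfp=[iv(1.1, 1.4), iv(6.0, 6.3)],
            ),
            Stretch(
                id="b",
                length=5.0,
                zip3=[iv(2.0, 2.8, Label.ZIP3)],
                gfp=[iv(2.1, 2.5), iv(0.2, 0.5), iv(4.0, 4.2)],
            ),
            Stretch(id="c", length=4.0, zip3=[], gfp=[iv(1.0, 1.3)]),
        ],
        name="three",
    )
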
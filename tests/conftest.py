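from datetime import datetime

import pytest

import stressense as ss


@pytest.fixture(scope="session")
def lex():
    return ss.fixture_lexicon()


@pytest.fixture
def worked_example_tweet():
    """A one-sentence, three-clause tweet mixing academic and
    interpersonal stress; clause 3 has no categorical word of its own."""
    return ss.Tweet(
        tweet_id="t-worked", user_id="u1",
        text="Terrible grade, hypocritical friendship, my world is really bad!!!",
        posted_at=datetime(2014, 3, 10, 22, 30),
    )


@pytest.fixture
def unknown_category_tweet():
    """A stressful tweet whose category is revealed only by the teen's
    response to a friend's comment."""
    return ss.Tweet(
        tweet_id="t-unknown", user_id="u1",
        text="I still feel sad.",
        posted_at=datetime(2014, 3, 10, 23, 45),
        comments=[ss.Comment(1, "f3", "What happened?")],
        responses=[ss.Response(1, "f3", "I broke up with my boyfriend.")],
    )


@pytest.fixture(scope="session")
def table1(lex):
    return ss.table1_corpus()
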
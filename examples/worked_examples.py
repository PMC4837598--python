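"""Per-category content features on two hand-sized example tweets.

Builds the two canonical inputs — a three-clause tweet mixing academic
and interpersonal stress, and a category-less tweet whose stress
category is revealed only by the teen's response to a friend — and
prints the extracted feature values.
"""

from datetime import datetime

import stressense as ss

lex = ss.fixture_lexicon()

multi = ss.Tweet(
    tweet_id="ex1", user_id="u1",
    text="Terrible grade, hypocritical friendship, my world is really bad!!!",
    posted_at=datetime(2014, 3, 10, 22, 30),
)
fw = ss.fw_content_features(multi, lex)
print("tweet:", multi.text)
print("  detected categories:", sorted(fw.cs))
print("  NegEmotion(academic)      =", fw.fw1["academic"])
print("  NegEmotion(interpersonal) =", fw.fw1["interpersonal"])
print("  PunctuationNum(academic)  =", fw.fw4["academic"])
# Clause 3 has no categorical word: it inherits academic+interpersonal
# from its sentence, so its "really bad" pair (degree 2) counts in both
# categories on top of each clause's own degree-1 negative word.

unknown = ss.Tweet(
    tweet_id="ex2", user_id="u1",
    text="I still feel sad.",
    posted_at=datetime(2014, 3, 10, 23, 45),
    comments=[ss.Comment(1, "f3", "What happened?")],
    responses=[ss.Response(1, "f3", "I broke up with my boyfriend.")],
)
tf = ss.assemble_vectors(unknown, lex)
print("\ntweet:", unknown.text)
print("  tweet categories CS:", sorted(tf.cs),
      " response categories CSR:", sorted(tf.csr))
print("  FW1(unknown)    =", ss.fw_content_features(unknown, lex).fw1["unknown"])
print("  FWC1(affection) =", tf.vectors["affection"].fwc1)
# The tweet alone reveals no category (one negative unit under
# "unknown"); the response mentions "boyfriend", so the unknown-category
# feature values are copied to the affection vector.

units = ss.neg_emotion_units(ss.default_tokenizer("not so happy", lex), lex)
u = units[0]
print("\n'not so happy' ->", u.effective_polarity, "unit, degree", u.degree,
      ", contribution", u.contribution)
# "not" flips the positive word negative and converts the strong adverb
# "so" (degree 3) to light (degree 1) — the same score as "a little unhappy".
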
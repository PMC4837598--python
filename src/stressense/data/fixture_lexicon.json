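{
 "categorical": {
  "grade": ["academic"],
  "homework": ["academic"],
  "school": ["academic"],
  "exam": ["academic"],
  "friendship": ["interpersonal"],
  "classmate": ["interpersonal"],
  "quarrel": ["interpersonal"],
  "boyfriend": ["affection"],
  "girlfriend": ["affection"],
  "crush": ["affection"],
  "myself": ["self-cognition"],
  "appearance": ["self-cognition"],
  "confidence": ["self-cognition"]
 },
 "neg_words": [
  "terrible",
  "hypocritical",
  "bad",
  "sad",
  "unhappy",
  "awful",
  "miserable",
  "upset",
  "hopeless",
  "lonely"
 ],
 "pos_words": [
  "happy",
  "glad",
  "great"
 ],
 "degree_adverbs": {
  "really": 2,
  "so": 3,
  "a little": 1,
  "very": 2,
  "extremely": 3,
  "slightly": 1
 },
 "negators": [
  "not",
  "never"
 ],
 "neg_emoticons": [
  ":(",
  ":-(",
  "T_T",
  "QAQ"
 ],
 "caring_markers": [
  "what happened",
  "don't worry",
  "cheer up",
  "what's up",
  "everything will be ok",
  "(hug)"
 ],
 "sad_music_titles": [
  "requiem for a dream",
  "the sound of silence"
 ]
}
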
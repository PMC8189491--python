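"""Default keyword and background vocabularies for the synthetic city.

The shipped keyword set has 88 entries across four categories (symptom,
disease, medication, smoking), mirroring the scale of a curated respiratory
illness dictionary built from word-embedding expansion plus a medication
list from the medical literature.  It is a realism fixture: nothing in the
pipeline depends on the exact count.
"""

from __future__ import annotations

SEED_TERMS: tuple[str, ...] = ("asthma", "copd", "smoking")

_SYMPTOMS = [
    "cough", "wheezing", "migraine", "anxiety", "breathless", "dyspnea",
    "phlegm", "mucus", "congestion", "tightness", "fatigue", "sneezing",
    "hoarseness", "snoring", "insomnia", "heartburn", "dizziness",
    "palpitations", "itchiness", "rash",
]

_DISEASES = [
    "asthma", "copd", "bronchitis", "pneumonia", "sepsis", "sinus",
    "emphysema", "sinusitis", "influenza", "flu", "tuberculosis", "apnea",
    "eczema", "rhinitis", "allergy", "fibrosis", "laryngitis", "pleurisy",
]

# Common asthma/COPD medication names; first five match the curated
# medication examples, incruse and ketamine appear among top predictors.
MEDICATION_TERMS: list[str] = [
    "inhaler", "advair", "symbicort", "ventolin", "proair", "incruse",
    "ketamine", "albuterol", "salbutamol", "flovent", "qvar", "pulmicort",
    "singulair", "montelukast", "prednisone", "spiriva", "breo", "anoro",
    "trelegy", "dulera", "xopenex", "atrovent", "combivent", "nebulizer",
    "budesonide", "fluticasone", "salmeterol", "formoterol", "tiotropium",
    "theophylline",
]

_SMOKING = [
    "cigarette", "nicotine", "cigs", "juul", "vape", "tobacco", "smoking",
    "ecig", "vaping", "hookah", "menthol", "smokeless", "chantix",
    "nicorette", "snus", "cigar", "rollies", "shisha", "quitting", "zyn",
]

DEFAULT_KEYWORDS: dict[str, str] = {}
for _term in _SYMPTOMS:
    DEFAULT_KEYWORDS[_term] = "symptom"
for _term in _DISEASES:
    DEFAULT_KEYWORDS[_term] = "disease"
for _term in MEDICATION_TERMS:
    DEFAULT_KEYWORDS[_term] = "medication"
for _term in _SMOKING:
    DEFAULT_KEYWORDS[_term] = "smoking"

assert len(DEFAULT_KEYWORDS) == 88

# Everyday, disease-unrelated search tokens used as query background noise.
BACKGROUND_VOCAB: list[str] = [
    "weather", "news", "recipe", "recipes", "movie", "movies", "football",
    "basketball", "baseball", "soccer", "score", "scores", "lyrics", "song",
    "music", "video", "videos", "game", "games", "phone", "laptop", "tablet",
    "charger", "shoes", "dress", "jacket", "sale", "coupon", "deals",
    "restaurant", "pizza", "burger", "sushi", "coffee", "tea", "bakery",
    "hotel", "flight", "flights", "airport", "train", "bus", "taxi", "map",
    "directions", "traffic", "parking", "bank", "loan", "mortgage", "rent",
    "apartment", "house", "garden", "furniture", "paint", "plumber",
    "electrician", "mechanic", "tires", "oil", "insurance", "taxes",
    "salary", "jobs", "resume", "interview", "college", "university",
    "school", "homework", "math", "history", "science", "translate",
    "dictionary", "calculator", "calendar", "email", "login", "password",
    "account", "wifi", "internet", "printer", "camera", "photos",
    "wallpaper", "haircut", "salon", "gym", "yoga", "running", "hiking",
    "camping", "fishing", "beach", "park", "zoo", "museum", "concert",
    "tickets", "festival", "birthday", "wedding", "gift", "gifts",
    "flowers", "cake", "chocolate", "wine", "beer", "cocktail", "grocery",
    "market", "pharmacy", "library", "bookstore", "novel", "comics",
    "anime", "cartoon", "celebrity", "gossip", "horoscope", "quotes",
    "jokes", "memes", "puzzle", "crossword", "sudoku", "chess", "poker",
    "lottery", "stocks", "crypto", "bitcoin", "gold", "silver", "dollar",
    "euro", "election", "president", "senate", "mayor", "city", "county",
    "state", "country", "world", "ocean", "mountain", "river", "lake",
    "desert", "forest", "rain", "snow", "storm", "sunny", "cloudy",
    "temperature", "forecast", "holiday", "vacation", "cruise", "passport",
    "visa", "luggage", "dog", "cat", "puppy", "kitten", "bird", "fish",
    "hamster", "vet",
]
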
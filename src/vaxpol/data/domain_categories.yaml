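# Default domain -> category assignment for popular base URLs in the vaccine
# discourse.  Categories: commercial (online store selling health-related
# products), conspiracy, news, pseudoscience, science, social_media, youtube.
# A domain may carry several categories.  Subdomain-bearing entries (e.g.
# articles.mercola.com) are kept verbatim; lookups fall back to the parent
# domain when the exact host is absent.
articles.mercola.com: [commercial]
awarenessact.com: [conspiracy]
bbc.co.uk: [news]
bbc.com: [news]
bioportfolio.com: [news, science]
cbc.ca: [news]
cdc.gov: [science]
choice.npr.org: [news]
cnn.com: [news]
collective-evolution.com: [conspiracy, pseudoscience]
edition.cnn.com: [news]
facebook.com: [social_media]
forbes.com: [news]
foxnews.com: [news]
go.thetruthaboutvaccines.com: [commercial]
greenmedinfo.com: [commercial]
healthimpactnews.com: [commercial]
healthnutnews.com: [commercial]
huffingtonpost.com: [news]
infowars.com: [commercial]
inshapetoday.com: [conspiracy, pseudoscience]
instagram.com: [social_media]
medicalnewstoday.com: [news, science]
naturalnews.com: [commercial]
nbcnews.com: [news]
newspunch.com: [conspiracy]
newstarget.com: [commercial, conspiracy]
nytimes.com: [news]
realfarmacy.com: [conspiracy, pseudoscience]
reddit.com: [social_media]
reuters.com: [news]
sciencedaily.com: [news, science]
seattleorganicrestaurants.com: [pseudoscience]
statnews.com: [news, science]
theguardian.com: [news]
time.com: [news]
vaccineimpact.com: [commercial]
webmd.com: [science]
whitehouse.gov: [news]
worldtruth.tv: [conspiracy]
youtube.com: [youtube]
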
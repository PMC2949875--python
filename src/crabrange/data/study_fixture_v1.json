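{
 "seed": 20109,
 "params": {
  "d": 0.0039,
  "e": 0.00032,
  "model": "DEC",
  "hypothesis": "HIA",
  "root_range": "A",
  "root_age": 47.23
 },
 "node_truth": {
  "0": "A",
  "1": "A",
  "6": "A",
  "7": "A",
  "46": "A",
  "47": "A",
  "104": "A",
  "105": "A",
  "108": "A",
  "109": "A",
  "110": "A",
  "111": "A",
  "112": "A",
  "106": "A",
  "107": "A",
  "48": "A",
  "83": "A",
  "84": "AB",
  "85": "A",
  "86": "A",
  "95": "A",
  "96": "A",
  "101": "A",
  "102": "A",
  "103": "A",
  "97": "A",
  "100": "A",
  "98": "A",
  "99": "A",
  "87": "A",
  "90": "A",
  "91": "A",
  "92": "A",
  "93": "A",
  "94": "A",
  "88": "A",
  "89": "A",
  "49": "A",
  "58": "A",
  "59": "A",
  "72": "A",
  "73": "A",
  "76": "A",
  "77": "A",
  "82": "A",
  "78": "A",
  "79": "A",
  "80": "A",
  "81": "A",
  "74": "A",
  "75": "A",
  "60": "AB",
  "69": "A",
  "70": "A",
  "71": "A",
  "61": "A",
  "62": "B",
  "63": "B",
  "68": "BC",
  "64": "B",
  "65": "B",
  "66": "B",
  "67": "B",
  "50": "A",
  "57": "A",
  "51": "AB",
  "56": "A",
  "52": "AB",
  "55": "B",
  "53": "AB",
  "54": "B",
  "8": "A",
  "29": "A",
  "30": "A",
  "35": "A",
  "36": "A",
  "39": "A",
  "40": "A",
  "41": "A",
  "42": "A",
  "45": "A",
  "43": "A",
  "44": "A",
  "37": "A",
  "38": "A",
  "31": "A",
  "32": "A",
  "33": "A",
  "34": "A",
  "9": "A",
  "24": "A",
  "25": "A",
  "28": "A",
  "26": "A",
  "27": "A",
  "10": "A",
  "13": "A",
  "14": "A",
  "17": "A",
  "18": "A",
  "19": "A",
  "20": "A",
  "21": "A",
  "22": "A",
  "23": "A",
  "15": "A",
  "16": "A",
  "11": "A",
  "12": "A",
  "2": "A",
  "3": "A",
  "4": "A",
  "5": "A"
 },
 "version": "1"
}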